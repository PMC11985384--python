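,Wake,N1,N2,N3,REM
Wake,16017,1240,1331,57,370
N1,964,2010,1084,18,186
N2,2329,785,34417,3529,1157
N3,93,5,1395,4836,51
REM,587,207,1154,84,7880
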