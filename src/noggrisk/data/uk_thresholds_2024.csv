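outcome,age,lat,it,uat,vhrt
mof,50,3.4,7.3,8.8,11.7
mof,55,4.5,9.5,11.4,15.2
mof,60,6.0,12.2,14.6,19.4
mof,65,8.6,16.5,19.8,26.4
mof,70,11.1,20.3,24.4,32.5
hip,50,0.23,0.91,1.1,1.5
hip,55,0.43,1.5,1.7,2.3
hip,60,0.80,2.3,2.8,3.7
hip,65,1.4,3.5,4.2,5.6
hip,70,2.6,5.4,6.5,8.6
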