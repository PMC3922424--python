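name,hemisphere,x,y,z,network,is_language
Br,L,-31.5,-28.5,-19.5,left-lateralized,True
We,L,-22.5,19.5,-16.5,left-lateralized,True
PC,L,-16.5,1.5,-10.5,left-lateralized,False
MP,L,-7.5,-16.5,-4.5,left-lateralized,False
TP,L,-1.5,31.5,-1.5,left-lateralized,False
MT,L,-25.5,19.5,4.5,left-lateralized,False
LP,L,-16.5,1.5,10.5,left-lateralized,False
lS,L,-10.5,-16.5,16.5,left-lateralized,False
SF,L,-1.5,31.5,19.5,left-lateralized,False
AI,R,4.5,-31.5,-19.5,right-lateralized,False
Bh,R,16.5,-7.5,-16.5,right-lateralized,False
DL,R,28.5,16.5,-13.5,right-lateralized,False
DP,R,10.5,-19.5,-7.5,right-lateralized,False
FE,R,22.5,4.5,-4.5,right-lateralized,False
IP,R,4.5,-31.5,1.5,right-lateralized,False
LIP,R,13.5,-7.5,4.5,right-lateralized,False
MC,R,25.5,16.5,7.5,right-lateralized,False
MI,R,7.5,-19.5,13.5,right-lateralized,False
PO,R,19.5,4.5,16.5,right-lateralized,False
rS,R,31.5,28.5,19.5,right-lateralized,False
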