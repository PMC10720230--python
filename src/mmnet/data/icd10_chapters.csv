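start,end,chapter
A00,B99,1
C00,D48,2
D50,D89,3
E00,E90,4
F00,F99,5
G00,G99,6
H00,H59,7
H60,H95,8
I00,I99,9
J00,J99,10
K00,K93,11
L00,L99,12
M00,M99,13
N00,N99,14
O00,O99,15
P00,P96,16
Q00,Q99,17
R00,R99,18
S00,T98,19
V01,Y98,20
Z00,Z99,21
U00,U99,22
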