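id,class,tail,head,length_um,inner_diameter_um
V_E_1,edge,IN,t1,3.0e2,5.6
V_E_2,edge,t1,t2,4.2e2,4.4
V_E_3,edge,t2,t3,1.2e3,4.5
V_E_4,edge,t3,t4,6.4e2,3.1
V_E_5,edge,t4,t5,2.2e2,1.9
V_E_6,edge,t5,t6,8.7e2,1.7
V_E_7,edge,t6,OUT,1.9e3,2.2
V_B_1,base,IN,b1,3.1e2,12.0
V_B_2,base,b1,b2,8.7e1,9.9
V_B_3,base,b2,b3,2.2e2,3.4
V_B_4,base,b3,b4,3.3e2,3.4
V_B_5,base,b4,b5,6.9e1,3.4
V_B_6,base,b5,b6,6.1e2,2.7
V_B_7,base,b6,OUT,4.0e2,5.7
V_C_1,connecting,t1,b1,7.6e1,3.9
V_C_2,connecting,t2,b2,3.7e2,5.8
V_C_3,connecting,t3,b3,1.3e3,2.6
V_C_4,connecting,t4,b4,1.4e3,3.1
V_C_5_E,connecting,t5,A,9.3e2,2.5
V_C_5_B,connecting,A,b5,4.5e2,2.8
V_C_6_E,connecting,t6,P,3.3e2,2.5
V_C_6_B,connecting,P,b6,1.0e3,2.7
PCV,cross,A,P,1.8e2,3.1
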