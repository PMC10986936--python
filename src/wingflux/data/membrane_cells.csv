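cell_id,surface_area_um2,printed_contact_area_um2,bounding_vein_ids
M1,1.7e4,2.0e3,V_E_1;V_C_1;V_B_1
M2,7.3e4,4.4e3,V_E_2;V_C_1;V_C_2;V_B_2
M3,3.2e5,1.6e4,V_E_3;V_C_2;V_C_3;V_B_3
M4,5.8e5,1.3e4,V_E_4;V_C_3;V_C_4;V_B_4
M5,5.9e5,8.4e3,V_E_5;V_C_4;V_C_5_E;V_C_5_B;V_B_5
M6_E,5.2e5,4.2e3,V_E_6;V_C_5_E;V_C_6_E;PCV
M6_B,2.2e5,5.7e3,V_B_6;V_C_5_B;V_C_6_B;PCV
M7,8.0e5,6.2e3,V_E_7;V_C_6_E;V_C_6_B;V_B_7
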