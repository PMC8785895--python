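label	x	y	z
DMN_mPFC_1	1	51	-2
DMN_mPFC_2	-2	55	-5
DMN_dmPFC_1	4	52	24
DMN_dmPFC_2	-4	54	25
DMN_vmPFC_1	1	46	-11
DMN_vmPFC_2	3	47	-10
DMN_ACC_rostral_1	2	43	8
DMN_ACC_rostral_2	-3	36	12
DMN_PCC_1	1	-47	26
DMN_PCC_2	-4	-51	29
DMN_Precuneus_1	3	-67	34
DMN_Precuneus_2	-4	-58	38
DMN_Retrosplenial_1	-3	-60	5
DMN_Retrosplenial_2	-4	-51	14
DMN_AngularGyrus_L	-51	-63	32
DMN_AngularGyrus_R	46	-60	32
DMN_MidTemporal_L	-62	-20	-8
DMN_MidTemporal_R	55	-21	-13
DMN_SupFrontal_L	-26	38	46
DMN_SupFrontal_R	25	34	46
DMN_InfTemporal_L	-64	-4	-20
DMN_InfTemporal_R	59	-13	-22
DMN_Parahippocampal_L	-25	-30	-23
DMN_Parahippocampal_R	29	-27	-20
DMN_TemporalPole_L	-43	19	-37
DMN_TemporalPole_R	43	17	-29
DMN_LatParietal_L	-52	-51	28
DMN_LatParietal_R	47	-53	24
DMN_InfFrontal_L	-50	23	-9
DMN_InfFrontal_R	50	23	-7
DMN_SupTemporalSulcus_L	-55	-39	9
DMN_SupTemporalSulcus_R	49	-45	3
DMN_AngularGyrus2_L1	-47	-65	40
DMN_MidTemporal2_R1	51	-20	-6
DMN_LatParietal2_L2	-52	-59	23
DMN_AngularGyrus2_R2	48	-61	40
DMN_MidTemporal2_L3	-61	-19	-19
DMN_LatParietal2_R3	51	-44	28
DMN_AngularGyrus2_L4	-52	-60	39
DMN_MidTemporal2_R4	52	-17	-20
DMN_LatParietal2_L5	-46	-50	22
DMN_AngularGyrus2_R5	45	-61	29
DMN_MidTemporal2_L6	-62	-24	-14
DMN_LatParietal2_R6	52	-57	16
DMN_AngularGyrus2_L7	-43	-61	28
DMN_MidTemporal2_R7	52	-26	-14
DMN_LatParietal2_L8	-53	-51	22
DMN_AngularGyrus2_R8	51	-62	29
DMN_MidTemporal2_L9	-61	-26	-7
DMN_LatParietal2_R9	56	-44	25
DMN_AngularGyrus2_L10	-39	-67	30
DMN_MidTemporal2_R10	65	-20	-8
DMN_LatParietal2_L11	-44	-57	21
DMN_AngularGyrus2_R11	48	-56	28
DMN_MidTemporal2_L12	-51	-27	-13
DMN_LatParietal2_R12	45	-52	32
DMN_AngularGyrus2_L13	-38	-62	30
DMN_MidTemporal2_R13	65	-29	-12
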