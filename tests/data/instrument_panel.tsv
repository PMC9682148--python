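name	chains	channel	q1_printed	q3_printed	dp	ep	ce	cxp
MG-17:0	17:0	acylium	362.3	253.3	60	10	21	14
MG-17:1	17:1	acylium	360.2	251.2	60	10	15	14
MG-19:0	19:0	nh3_h2o_loss	390.3	355.3	60	10	19	18
MG-19:1	19:1	acylium	388.3	279.1	60	10	15	14
MG-19:2	19:2	acylium	386.3	277.1	60	10	15	14
MG-21:0	21:0	nh3_h2o_loss	418.3	383.3	60	10	19	20
MG-22:1	22:1	acylium	430.3	321.3	60	10	21	18
MG-24:1	24:1	acylium	458.3	349.3	60	10	21	18
DG-31:1[D5]	17:0/14:1	acyl_loss:14:1	575.5	332.2	50	10	21	18
DG-33:1[D5]	17:0/16:1	acyl_loss:17:0	603.4	316.4	50	10	21	18
DG-35:1[D5]	17:0/18:1	acyl_loss:17:0	631.6	344.2	50	10	27	18
DG-37:3[D5]	17:0/20:3	acyl_loss:17:0	655.4	368.4	50	10	27	18
DG-39:4[D5]	17:0/22:4	acyl_loss:22:4	681.6	332.2	50	10	27	18
DG-44:2	22:1/22:1	acyl_loss:22:1	750.7	395.4	50	10	26	15
DG-48:2	24:1/24:1	acyl_loss:24:1	806.7	423.4	50	10	31	24
TG-41:0[D5]	14:0/13:0/14:0	acyl_loss:14:0	731.4	486.4	80	10	33	24
TG-43:1[D5]	14:0/15:1/14:0	acyl_loss:14:0	757.4	512.4	80	10	33	24
TG-45:1[D5]	14:0/17:1/14:0	acyl_loss:14:0	785.5	540.6	80	10	33	24
TG-47:1[D5]	16:0/15:1/16:0	acyl_loss:16:0	813.4	540.4	80	10	39	18
TG-49:1[D5]	16:0/17:1/16:0	acyl_loss:16:0	841.4	568.4	80	10	33	24
TG-51:2[D5]	16:0/19:2/16:0	acyl_loss:16:0	867.4	594.4	80	10	37	16
TG-53:3[D5]	18:1/17:1/18:1	acyl_loss:18:1	893.8	594.6	80	10	37	16
TG-54:9	18:3/18:3/18:3	acyl_loss:18:3	890.8	595.6	80	10	37	28
TG-55:4[D5]	18:1/19:2/18:1	acyl_loss:18:1	919.6	620.6	80	10	39	18
TG-57:4[D5]	18:1/21:2/18:1	acyl_loss:18:1	947.8	648.6	80	10	39	18
TG-66:3	22:1/22:1/22:1	acyl_loss:22:1	1071.1	715.8	80	10	43	32
TG-72:3	24:1/24:1/24:1	acyl_loss:24:1	1155.4	771.8	80	10	43	32
MGDG-34:0	16:0/18:0	carboxylate:18:0	757.6	283.2	-80	-10	-30	-15
DGDG-36:0	18:0/18:0	carboxylate:18:0	947.7	283.2	-180	-10	-40	-15
LPC-15:0[D5]	15:0	carboxylate:15:0	545.4	241.2	-40	-10	-40	-13
LPC-17:0[D5]	17:0	carboxylate:17:0	573.4	269.2	-40	-10	-40	-13
LPC-19:0[D5]	19:0	carboxylate:19:0	601.4	297.3	-40	-10	-40	-13
LPC-17:1	17:1	carboxylate:17:1	566.4	267.2	-40	-10	-40	-13
LPE-15:0[D5]	15:0	carboxylate:15:0	443.4	241.2	-110	-10	-30	-13
LPE-17:0[D5]	17:0	carboxylate:17:0	471.4	269.1	-110	-10	-30	-13
LPE-19:0[D5]	19:0	carboxylate:19:0	499.4	297.3	-110	-10	-30	-13
LPE-18:1	18:1	carboxylate:18:1	478.3	281.3	-110	-10	-30	-13
LPG-15:0[D5]	15:0	carboxylate:15:0	474.3	241.1	-100	-10	-34	-17
LPG-17:0[D5]	17:0	carboxylate:17:0	502.3	269.2	-100	-10	-34	-17
LPG-19:0[D5]	19:0	carboxylate:19:0	530.4	297.2	-100	-10	-34	-17
LPG-17:1	17:1	carboxylate:17:1	495.2	267.2	-100	-10	-34	-17
LPI-15:0[D5]	15:0	carboxylate:15:0	562.4	241.2	-110	-10	-44	-13
LPI-17:0[D5]	17:0	carboxylate:17:0	590.2	269.3	-110	-10	-44	-13
LPI-19:0[D5]	19:0	carboxylate:19:0	618.4	297.2	-110	-10	-44	-13
LPI-18:1	18:1	carboxylate:18:1	597.3	281.3	-110	-10	-44	-13
LPS-15:0[D5]	15:0	headgroup_d5	487.4	158.0	-40	-10	-34	-9
LPS-17:0[D5]	17:0	headgroup_d5	515.4	158.0	-40	-10	-34	-9
LPS-19:0[D5]	19:0	headgroup_d5	543.3	158.0	-40	-10	-34	-9
LPS-17:1	17:1	carboxylate:17:1	508.4	267.2	-40	-10	-34	-9
PC-31:1[D5]	14:1/17:0	carboxylate:14:1	781.6	225.2	-65	-10	-52	-15
PC-33:1[D5]	16:1/17:0	carboxylate:16:1	809.6	253.2	-65	-10	-52	-15
PC-35:1[D5]	18:1/17:0	carboxylate:18:1	837.6	281.2	-65	-10	-52	-15
PC-37:3[D5]	20:3/17:0	carboxylate:20:3	861.6	305.2	-65	-10	-52	-15
PC-39:4[D5]	22:4/17:0	carboxylate:22:4	887.6	331.2	-65	-10	-52	-15
PE-31:1[D5]	14:1/17:0	carboxylate:14:1	679.4	225.2	-120	-10	-38	-13
PE-33:1[D5]	16:1/17:0	carboxylate:16:1	707.6	253.2	-120	-10	-38	-13
PE-35:1[D5]	18:1/17:0	carboxylate:18:1	735.6	281.4	-120	-10	-38	-13
PE-37:3[D5]	20:3/17:0	carboxylate:20:3	759.6	305.2	-120	-10	-38	-13
PE-39:4[D5]	22:4/17:0	carboxylate:22:4	785.6	331.2	-120	-10	-38	-13
PG-31:1[D5]	14:1/17:0	carboxylate:14:1	710.6	225.2	-120	-10	-44	-13
PG-33:1[D5]	16:1/17:0	carboxylate:16:1	738.4	253.2	-120	-10	-44	-13
PG-35:1[D5]	18:1/17:0	carboxylate:18:1	766.5	281.3	-120	-10	-44	-13
PG-37:3[D5]	20:3/17:0	carboxylate:20:3	790.4	305.2	-120	-10	-44	-13
PG-39:4[D5]	22:4/17:0	carboxylate:22:4	816.4	331.2	-120	-10	-44	-13
PI-31:1[D5]	14:1/17:0	carboxylate:17:0	798.6	269.2	-55	-10	-60	-15
PI-33:1[D5]	16:1/17:0	carboxylate:16:1	826.6	253.2	-55	-10	-60	-15
PI-35:1[D5]	18:1/17:0	carboxylate:18:1	854.6	281.2	-55	-10	-60	-15
PI-37:3[D5]	20:3/17:0	carboxylate:20:3	878.6	305.2	-55	-10	-60	-15
PI-39:4[D5]	22:4/17:0	carboxylate:22:4	904.6	331.2	-55	-10	-60	-15
PS-31:1[D5]	14:1/17:0	carboxylate:17:0	723.6	269.3	-60	-10	-50	-13
PS-33:1[D5]	16:1/17:0	carboxylate:16:1	751.6	253.2	-60	-10	-50	-13
PS-35:1[D5]	18:1/17:0	carboxylate:17:0	779.6	269.3	-60	-10	-50	-13
PS-37:3[D5]	20:3/17:0	carboxylate:20:3	803.6	305.2	-60	-10	-50	-13
PS-39:4[D5]	22:4/17:0	carboxylate:22:4	829.6	331.2	-60	-10	-50	-13
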