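# Targeted-NGS validation cohort for the coverage-asymmetry ALK fusion predictor.
# predicted_positive: coverage-asymmetry call (one-sided exact MWU p < 0.05).
# confirmed_positive: ALK fusion detected by at least one targeted fusion panel
# (TruSight RNA Fusion or OncoFu Elite).
# The 19 named samples are individually reported validation cases; the 31 CTRL_*
# rows are synthetic placeholders for the panel-negative, asymmetry-negative
# controls that are only reported in aggregate (predicted and confirmed both
# negative for every one of them).
sample_id	predicted_positive	confirmed_positive
ALK_1_2	1	1
ALK_2	1	1
ALK_3	0	0
ALK_4	1	1
ALK_5	1	1
ALK_6_2	0	0
ALK_8	1	1
ALK_9	1	1
ALK_10	1	1
ALK_12	1	1
ALK_14	0	0
ALK_15	0	0
ALK_16	1	1
LuC_62	1	1
LuC_68	1	0
LuC_103	0	0
LuC_104	1	1
NS_20	0	0
OC_25	1	0
CTRL_01	0	0
CTRL_02	0	0
CTRL_03	0	0
CTRL_04	0	0
CTRL_05	0	0
CTRL_06	0	0
CTRL_07	0	0
CTRL_08	0	0
CTRL_09	0	0
CTRL_10	0	0
CTRL_11	0	0
CTRL_12	0	0
CTRL_13	0	0
CTRL_14	0	0
CTRL_15	0	0
CTRL_16	0	0
CTRL_17	0	0
CTRL_18	0	0
CTRL_19	0	0
CTRL_20	0	0
CTRL_21	0	0
CTRL_22	0	0
CTRL_23	0	0
CTRL_24	0	0
CTRL_25	0	0
CTRL_26	0	0
CTRL_27	0	0
CTRL_28	0	0
CTRL_29	0	0
CTRL_30	0	0
CTRL_31	0	0
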