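name	ecoli_ug_ml	ecoli_um	saureus_ug_ml	saureus_um	source
ocellatin-1	*	*	NT	NT	zone assay only
ocellatin-2	*	*	NT	NT	zone assay only
ocellatin-3	*	*	NT	NT	zone assay only
ocellatin-4	145	64	145	64	prior literature
ocellatin-5	64	28	128	56	prior literature
ocellatin-6	32	14	64	28	prior literature
ocellatin-F	106	40	>60	>160	prior literature
ocellatin-F1	1060	397	293	110	prior literature
ocellatin-P	64	25	508	200	prior literature
ocellatin-PT1	800	300	>800	>300	prior literature
ocellatin-PT2	>800	>310	>800	>310	prior literature
ocellatin-PT3	800	320	>800	>320	prior literature
ocellatin-PT4	200	80	>800	>310	prior literature
ocellatin-PT5	800	300	>800	>300	prior literature
ocellatin-PT6	400	120	>800	>240	prior literature
ocellatin-PT7	200	60	800	245	prior literature
ocellatin-PT8	200	60	800	245	prior literature
ocellatin-L1	128	50	512	>200	prior literature
ocellatin-L2	I	I	I	I	prior literature
ocellatin-S	NT	NT	I	I	prior literature
ocellatin-V1	512	>200	512	>200	prior literature
ocellatin-V2	514	>200	514	>200	prior literature
ocellatin-V3	I	I	I	I	prior literature
ocellatin-K1	NI	NI	NI	NI	prior literature
P3-Lla-2085	31	15	31	15	prior literature
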