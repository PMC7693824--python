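name	parent	start	end	species	source
ocellatin-S (1-16)	ocellatin-S	1	16	Leptodactylus syphax	skin secretion fragment
ocellatin-S (1-22)	ocellatin-S	1	22	Leptodactylus syphax	skin secretion fragment
ocellatin-S (1-23)	ocellatin-S	1	23	Leptodactylus syphax	skin secretion fragment
ocellatin-S (1-24)	ocellatin-S	1	24	Leptodactylus syphax	skin secretion fragment
ocellatin-S (16-25)	ocellatin-S	16	25	Leptodactylus syphax	skin secretion fragment
ocellatin-K1 (1-16)	ocellatin-K1	1	16	Leptodactylus vastus	skin secretion fragment
ocellatin-K1 (1-21)	ocellatin-K1	1	21	Leptodactylus vastus	skin secretion fragment
ocellatin-F (1-22)	ocellatin-F	1	22	Leptodactylus fallax	reclassified from ocellatin-LB1
ocellatin-F (1-23)	ocellatin-F	1	23	Leptodactylus labyrinticus	reclassified from ocellatin-LB2
ocellatin-L1 (1-22)	ocellatin-L1	1	22	Leptodactylus laticeps	skin secretion fragment
ocellatin-1 (1-16)	ocellatin-1	1	16	Leptodactylus latrans	skin secretion fragment
ocellatin-2 (1-15)	ocellatin-2	1	15	Leptodactylus latrans	skin secretion fragment
ocellatin-3 (1-15)	ocellatin-3	1	15	Leptodactylus latrans	skin secretion fragment
ocellatin-5 (1-14)	ocellatin-5	1	14	Leptodactylus latrans	skin secretion fragment
ocellatin-6 (1-18)	ocellatin-6	1	18	Leptodactylus latrans	skin secretion fragment
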