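name	species	sequence	amidated	group	printed_mw	printed_charge	source
ocellatin-F	Leptodactylus fallax	GVVDILKGAAKDIAGHLASKVMNKL	yes	family_member			fallaxin; prior literature
ocellatin-K1	Leptodactylus knudseni	GVVDILKGAAKDLAGHLASKVMNKI	yes	family_member			prior literature; also in L. vastus
ocellatin-L1	Leptodactylus laticeps	GVVDILKGAAKDLAGHLATKVMNKL	yes	family_member			laticeptin; prior literature
ocellatin-L2	Leptodactylus laticeps	GVVDILKGAAKDLAGHLATKVMDKL	yes	family_member			prior literature
ocellatin-S	Leptodactylus syphax	GVLDILKGAAKDLAGHVATKVINKI	yes	family_member			syphaxin; prior literature
ocellatin-P	Leptodactylus pentadactylus	GLLDTLKGAAKNVVGSLASKVMEKL	yes	family_member			pentadactylin; prior literature
ocellatin-7	Leptodactylus latrans	GVVDILKDTGKKLLSHLMEKI	yes	family_member	2336.87	2	novel cDNA clone
ocellatin-8	Leptodactylus latrans	GVVDILKDTGKKLLSHLMEKV	yes	family_member	2322.84	2	novel cDNA clone
ocellatin-9	Leptodactylus latrans	GVLDIFKDTGKKLLSHLMEKV	yes	family_member	2370.89	1	novel cDNA clone
ocellatin-5	Leptodactylus latrans	AVLDILKDVGKGLLSHFMEKV	yes	family_member	2311.82	1	prior literature
ocellatin-10	Leptodactylus latrans	GLLDFLKAAGKGLVSNLIEKV	yes	family_member	2184.65	2	novel cDNA clone
ocellatin-6	Leptodactylus latrans	AVLDFIKAAGKGLVTNIMEKVG	ambiguous	family_member	2273.77	2	prior literature
ocellatin-PT6	Leptodactylus pustullatus	GVFDIIKGAGKQLIAHAMEKIAEKVGLNKDGN	no	family_member			prior literature
ocellatin-PT8	Leptodactylus pustullatus	GVFDIIKGAGKQLIARAMGKIAEKVGLNKDGN	no	family_member			prior literature
ocellatin-PT7	Leptodactylus pustullatus	GVFDIIKGAGKQLIAHAMGKIAEKVGLNKDGN	no	family_member			prior literature
ocellatin-PT4	Leptodactylus pustullatus	GVFDIIKGAGKQLIAHAMGKIAEKV	yes	family_member			prior literature
ocellatin-PT1	Leptodactylus pustullatus	GVFDIIKDAGKQLVAHAMGKIAEKV	yes	family_member			prior literature
ocellatin-PT5	Leptodactylus pustullatus	GVFDIIKDAGRQLVAHAMGKIAEKV	yes	family_member			prior literature
ocellatin-PT2	Leptodactylus pustullatus	GVFDIIKDAGKQLVAHATGKIAEKV	yes	family_member			prior literature
ocellatin-PT3	Leptodactylus pustullatus	GVIDIIKGAGKDLIAHAIGKLAEKV	yes	family_member			prior literature
ocellatin-V1	Leptodactylus validus	GVVDILKGAGKDLLAHALSKLSEKV	yes	family_member			prior literature
ocellatin-V3	Leptodactylus validus	GVLDILTGAGKDLLAHALSKLSEKV	yes	family_member			prior literature
ocellatin-V2	Leptodactylus validus	GVLDILKGAGKDLLAHALSKISEKV	yes	family_member			prior literature
ocellatin-1	Leptodactylus latrans	GVVDILKGAGKDLLAHLVGKISEKV	yes	family_member			prior literature
ocellatin-11	Leptodactylus latrans	GVLDIFKDAAKQILAHAAEKI	yes	family_member	2250.67	1	novel cDNA clone
ocellatin-2	Leptodactylus latrans	GVLDIFKDAAKQILAHAAEQI	yes	family_member	2250.63	0	prior literature
ocellatin-4	Leptodactylus latrans	GLLDFVTGVGKDIFAQLIKQI	yes	family_member			prior literature
ocellatin-3	Leptodactylus latrans	GVLDILKNAAKNILAHAAEQI	yes	family_member			prior literature
P3-Lla-2085	Leptodactylus latrans	GLLDFLKAAGKGLVSNLLEK	yes	analog	2085.52	2	synthetic hybrid analog
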