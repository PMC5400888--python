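# SYNTHETIC sentiment lexicon in SentiWordNet 3.0 file layout.
# This is a small hand-written stand-in shipped for tests and the synthetic
# corpus generator; a real SentiWordNet 3.0 download loads through the same
# reader. Columns: POS <TAB> ID <TAB> PosScore <TAB> NegScore <TAB> SynsetTerms <TAB> Gloss
a	00000010	0.5	0	good#1	having desirable qualities
a	00000011	0.125	0	good#2	not bad
n	00000020	0.125	0	luck#1	favorable outcome by chance
n	00000030	0.25	0	hope#1	expectation of a favorable outcome
a	00000040	0.375	0	best#1	most desirable
a	00000050	0	0.375	sorry#1	feeling regret or sympathy
a	00000060	0.75	0	happy#1	feeling joy or pleasure
a	00000070	0.625	0	hopeful#1	full of hope
a	00000080	0.75	0	wonderful#1	extraordinarily good
a	00000090	0.75	0	grateful#1	feeling thankful
a	00000100	0.625	0	relieved#1	freed from worry
a	00000110	0.625	0	glad#1	showing happiness
a	00000120	0.625	0	encouraged#1	inspired with confidence
a	00000130	0.625	0	thankful#1	feeling gratitude
a	00000140	0.75	0	joyful#1	full of joy
a	00000150	0.5	0	comforting#1	providing consolation
a	00000160	0.5	0	calm#1	free from agitation
a	00000161	0	0	calm#2	windless
a	00000170	0	0.75	scared#1	made afraid
a	00000180	0	0.625	worried#1	afflicted with anxiety
a	00000190	0	0.75	awful#1	exceptionally bad
a	00000200	0	0.75	terrible#1	causing fear or dread
a	00000210	0	0.625	sad#1	experiencing sorrow
a	00000220	0	0.75	depressed#1	low in spirits
a	00000230	0	0.625	anxious#1	full of anxiety
a	00000240	0	0.75	hopeless#1	without hope
a	00000250	0	0.75	frightened#1	thrown into fear
a	00000260	0	0.875	devastated#1	emotionally overwhelmed
a	00000270	0	0.75	miserable#1	deeply unhappy
a	00000280	0	0.625	upset#1	emotionally distressed
a	00000290	0	0.625	afraid#1	filled with fear
a	00000300	0	0.625	stressful#1	causing mental strain
v	00000310	0	0.5	crying#1	shedding tears
a	00000320	0	0.625	overwhelmed#1	overcome by pressure
a	00000330	0.625	0	optimistic#1	expecting the best
a	00000340	0.5	0	reassuring#1	restoring confidence
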