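index	Pterygoplichthys pardalis	Macrobrachium rosenbergii	Crassostrea gigas	Trachemys scripta elegans	Ambystoma mexicanum
p11	5	2	2	4	0
p12	0	0	0	0	1
p21	5	4	5	5	3
p22	4	4	4	5	3
p23	5	3	3	5	3
p24	4	4	3	5	1
p25	5	3	3	4	1
p26	4	4	3	5	1
p31	2	2	3	3	3
p32	1	1	1	1	1
p33	1	1	1	1	1
p34	1	1	1	1	1
p35	1	1	1	1	1
p36	1	1	1	1	1
p37	1	1	1	1	1
p38	2	2	1	1	2
p39	2	2	2	2	2
p41	4	4	3	2	3
p42	5	5	5	3	4
p43	1	1	1	1	1
p44	1	1	1	2	1
p51	1	1	1	1	1
p52	1	1	1	1	1
p53	1	1	1	1	1
p54	1	1	1	1	1
p55	1	1	1	1	1
p56	3	4	4	2	3
p57	2	2	2	2	2
p58	2	2	2	2	2
p59	1	1	1	1	1
p61	3	5	4	3	2
p62	4	4	3	2	3
p63	3	3	2	2	4
p64	3	3	2	2	4
p71	5	5	4	2	3
p72	5	5	4	3	4
p73	4	5	5	3	4
p74	2	2	2	1	1
p81	4	5	3	3	4
p82	5	5	4	3	4
p83	4	4	2	3	3
p91	5	5	4	3	4
p92	5	5	4	3	4
p93	4	5	4	2	3
p94	5	5	5	4	4
p101	5	5	5	4	4
p102	3	1	2	1	1
p103	4	1	2	1	2
p104	4	4	4	3	2
p111	5	5	5	3	3
p112	4	5	4	2	3
p113	4	5	4	1	3
p114	2	2	2	1	2
p115	5	5	4	3	4
p121	5	4	3	4	4
p122	4	4	4	3	3
p123	4	4	3	3	2
p124	5	4	2	4	3
p125	5	3	2	5	2
p126	5	3	2	4	3
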