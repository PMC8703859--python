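region_id	region_name
1	Middle Cerebellar Peduncle
2	Pontine Crossing Tract
3	Genu of Corpus Callosum
4	Body of Corpus Callosum
5	Splenium of Corpus Callosum
6	Fornix (Column and Body)
7	Corticospinal Tract R
8	Corticospinal Tract L
9	Medial Lemniscus R
10	Medial Lemniscus L
11	Inferior Cerebellar Peduncle R
12	Inferior Cerebellar Peduncle L
13	Superior Cerebellar Peduncle R
14	Superior Cerebellar Peduncle L
15	Cerebral Peduncle R
16	Cerebral Peduncle L
17	Anterior Limb of Internal Capsule R
18	Anterior Limb of Internal Capsule L
19	Posterior Limb of Internal Capsule R
20	Posterior Limb of Internal Capsule L
21	Retrolenticular Part of Internal Capsule R
22	Retrolenticular Part of Internal Capsule L
23	Anterior Corona Radiata R
24	Anterior Corona Radiata L
25	Superior Corona Radiata R
26	Superior Corona Radiata L
27	Posterior Corona Radiata R
28	Posterior Corona Radiata L
29	Posterior Thalamic Radiation R
30	Posterior Thalamic Radiation L
31	Sagittal Stratum R
32	Sagittal Stratum L
33	External Capsule R
34	External Capsule L
35	Cingulum Cingulate Gyrus R
36	Cingulum Cingulate Gyrus L
37	Cingulum Hippocampus R
38	Cingulum Hippocampus L
39	Fornix Cres/Stria Terminalis R
40	Fornix Cres/Stria Terminalis L
41	Superior Longitudinal Fasciculus R
42	Superior Longitudinal Fasciculus L
43	Superior Fronto-occipital Fasciculus R
44	Superior Fronto-occipital Fasciculus L
45	Uncinate Fasciculus R
46	Uncinate Fasciculus L
47	Tapetum R
48	Tapetum L
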