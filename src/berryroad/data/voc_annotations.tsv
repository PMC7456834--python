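mz	formula	identification
27.0263	C2H3+	
28.0184		
28.0314		
30.0435		
30.9952		
31.0455		
33.0331	CH4OH+	Methanol
34.9958	H2SH+	Hydrogen sulfide
39.0228	C3H3+	common fragment
41.0386	C3H5+	common fragment
42.0101	C2H2O+	
42.0225		
43.0153	C2H3O+	common fragment
43.0576	C3H7+	common fragment
44.058		
45.0319	C2H4OH+	Acetaldehyde
47.0102	CH3O2+	Formic acid
47.0193		
47.0436	C2H6OH+	Ethanol
49.0112	CH4SH+	Methanethiol
49.0277		
49.9991		
51.0059		
51.0431	CH3OH*H3O+	Methanol cluster
53.0039		
53.0396	C4H5+	common fragment
55.0171	C3H3O+	
55.0542	C4H7+	common fragment
57.0334	C3H4OH+	common fragment
57.0697	C4H9+	1-Octanol, high alcohol fragment
60.0214		
61.0233	C2H4O2H+	Acetic acid, common ester fragment
63.0083		
63.0329	C2H6SH+	Dimethyl sulfide, Ethanethiol
63.0425	C2H4O*H3O+	Ethanol cluster
65.02		
67.056	C5H7+	
69.0333	C4H4OH+	Furan
69.0699	C5H9+	Aldehyde fragment
71.0491	C4H6OH+	Butenal
71.0854	C5H11+	3-methyl-1-butanol + 2-methyl-1-butanol, Pentanol
73.0298	C3H4O2H+	
73.0646	C4H8OH+	Butanale, isobutyraldehyde
75.0436	C3H6O2H+	Methyl acetate
75.0803		
77.0223		
78.0465	C6H6+	
79.0374	C6H7+	Benzene
79.0739		
80.0559	C5[13]CH7+	
81.0701	C6H9+	Fragment of aldehydes (Hexenals); fragment of terpenes (Linalool)
83.0492	C5H6OH+	Methylfuran
83.0858	C6H11+	(E)-3-Hexen-1-ol, (Z)-3-Hexen-1-ol, (Z)-2-Hexen-1-ol, Hexanal, 2-Hexanone
85.028	C4H4O2H+	Furanone
85.0647	C5H8OH+	(E)-2-Pentenal
85.1008	C6H13+	Hexanol
87.0442	C4H6O2H+	Butyrolactone
87.081	C5H10OH+	2-methyl butanal+3-methyl butanal
89.055	C4H8O2H+	Ethyl acetate
89.1408		
89.201		
89.2685		
91.068	C7H7+	Benzyl Alcohol
93.0379	C3H8OSH+	2-(Methylthio)ethanol
93.9552		
94.0932		
95.0188		
95.0489	C6H6OH+	Phenol
95.0873	C7H11+	(E)-2-Heptenal, Monoterpene fragment
97.0274	C5H4O2H+	Furfural
97.0652	C6H8OH+	(E,Z)-2,4-Hexadienal, (E,E)-2,4-Hexadienal
99.0803	C6H10OH+	(Z)-3-Hexenal, (E)-2-Hexenal
101.023		
101.061	C5H8O2H+	2,3-Pentanedione, 2-Butenoic acid methyl ester
101.096	C6H12OH+	Hexanal
103.076	C5H10O2H+	Ethyl Propanoate
105.064	C8H9+	Phenetyl Alcohol. Styrene
106.08		
107.07	C7H6OH+	Benzaldehyde
107.087	C8H10H+	Ethyl Benzene, p-Xylene, m-Xylene
108.958		
109.034		
109.102	C8H13+	2-Octenal (E)
111.044		
111.081	C7H10OH+	(E,E)-2,4-Heptadienal
111.117	C8H15+	(E)-2-Octenal, Octanal,1-Octen-3-ol
113.06	C6H8O2H+	Sorbic acid
113.098	C7H12OH+	(E)-2-Heptenal
115.076	C6H10O2H+	Ethyl Crotonate, Ethyl (2E)-2-butenoate
115.114	C7H14OH+	2-Heptanone, Heptanal
117.092	C6H12O2H+	Ethyl Isobutanoate, Methyl-2-methyl butanoate, Methyl Isovalerate, Ethyl Butyrate, Hexanoic Acid
118.05		
118.981		
119.074	C9H11+	3-Phenylpropanol
121.068	C8H8OH+	Acetophenone, Phenylacetaldehyde
123.048		
123.118	C9H15+	2-Nonenal, (E)-2-Nonenal
123.946		
125.1	C8H12OH+	6-Methyl-3,5-heptadien-2-one
125.96		
126.904		
127.072		
127.113	C8H14OH+	1-octen-3-one, 6-methyl-5-hepten-2-one, (E)-2-Octenal.
129.092	C8H16OH+	2-octanone, Octanal, 1-Octen-3-ol
131.107	C7H14O2H+	Ethyl-2-methyl butanoate, Ethyl Isovalerate
133.103	C10H13+	Thymol
135.115	C10H15+	HO-Trienol
136.024		
136.99		
137.134	C10H17+	1.8-cineole, Linalool, 4-Terpineol, alpha Terpineol, Nerol, Geraniol* Beta myrcene, Limonene, (E)-Beta Ocimene, Alpha Terpinolene
139.076	C8H10O2H+	5,5-Dimethyl-2-cyclohexen-1,4-dione
139.117	C9H14OH+	
141.094	C9H16OH+	2-Nonenal, (E)-2-Nonenal, Ethyl sorbate
143.109	C8H14O2H+	(Z)-3-Hexenyl Acetate, 2-Hexenyl Acetate
143.145	C9H18OH+	2-Nonanone, Nonanal
144.915		
145.124	C8H16O2H+	Ethyl Hexanoate, Hexyl Acetate, Octanoic Acid
147.111		
151.113		
157.122	C9H16O2H+	γ-Nonalactone
157.16	C10H20OH+	Decanal
159.14	C9H18O2H+	Nonanoic Acid
161.107		
163.088		
165.094		
169.126		
171.138	C10H18O2H+	Linalool oxide, 2-Octenyl Acetate, gamma-Decalactone
171.177		
173.156	C10H20O2H+	Decanoic Acid
174.908		
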