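name	dataset	rank_npclassscore	rank_metcalf	standardised_metcalf	npclassscore
Staurosporine	Streptomyces/Salinispora	1	2	9.0	0.78
Rosamicin	Streptomyces/Salinispora	1 (6)	8 (38)	8.7	0.76
Desferrioxamine	Streptomyces/Salinispora	1	1	9.5	0.36
Rifamycin	Streptomyces/Salinispora	152	257	4.4	0.45
Lomaiviticin	Streptomyces/Salinispora	30 (18)	381 (151)	3.0	0.96
Arenimycin	Streptomyces/Salinispora	1 (4)	1 (12)	12.4	0.96
Enterocin	Streptomyces/Salinispora	1 (8)	4 (81)	12.4	0.40
Salinamide	Streptomyces/Salinispora	1 (40)	1 (84)	12.4	0.64
Cyclomarin	Streptomyces/Salinispora	3 (49)	4 (83)	8.7	0.91
Retimycin	Streptomyces/Salinispora	-	-	-	-
Actinomycin	Streptomyces/Salinispora	1 (97)	1 (159)	12.4	0.76
Anabaenopeptin	Cyanobacteria	2 (3)	3 (6)	4.2	0.93
Micropeptin	Cyanobacteria	-	discarded	-	1.00
Kawaguchipeptin	Cyanobacteria	1 (37)	2 (39)	4.7	0.71
Microcyclamide	Cyanobacteria	1 (13)	1 (18)	4.7	1.00
Microcystin	Cyanobacteria	11 (4)	13 (8)	3.2	0.64
Microcystin RR	Cyanobacteria	-	discarded	-	0.64
Mycobactin	Nocardia	1 (90)	2 (133)	3.2	0.64
Mycobactin	Nocardia	discarded	-	-	0.03
Nocardimicin	Nocardia	-	-	-	-
Nocobactin	Nocardia	-	discarded	-	0.59
Nocobactin	Nocardia	-	discarded	-	0.59
Nocobactin	Nocardia	-	discarded	-	0.64
Formobactin	Nocardia	1 (338)	4 (648)	2.12	0.64
Nocardimicin	Nocardia	2 (255)	11 (427)	2.12	0.59
Carboxynocobactin	Nocardia	1 (338)	4 (648)	2.12	0.46
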