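accession	role	n_survived	n_died	description	country	timing
E-MEXP-3567	discovery	6	6	Children with meningococcal sepsis +/- HIV co-infection	Malawi	Admission to ED
E-MEXP-3850	discovery	19	5	Children with meningococcal sepsis	UK	Admission to hospital; sampled at multiple times 0-48 h
E-MTAB-1548	discovery	50	24	Adult surgical patients with sepsis (EXPRESS study)	Spain	Average post-operation day 4 (hospital acquired)
GSE10474	discovery	22	11	Adults in MICU with sepsis +/- ALI	USA	Admission to ICU
GSE13015a	discovery	35	13	Adults with sepsis, many from burkholderia	Thailand	Within 48 h of diagnosis
GSE13015b	discovery	8	7	Adults with sepsis, many from burkholderia	Thailand	Within 48 h of diagnosis
GSE27131	discovery	5	2	Adults with severe H1N1 influenza requiring mechanical ventilation	Norway	Admission to ICU
GSE32707	discovery	31	17	Adults in MICU with sepsis +/- ARDS	USA	Admission to ICU
GSE40586	discovery	19	2	Infants, children, and adults with bacterial meningitis	Estonia	Within 48 h of hospital admission
GSE63042	discovery	76	28	Adults with sepsis (CAPSOD study)	USA	Admission to ED
GSE66099	discovery	171	28	Children in ICU with sepsis/septic shock	USA	Admission to ICU
GSE66890	discovery	43	14	Adults in ICU with sepsis +/- ARDS	USA	Admission to ICU
GSE21802	validation	7	4	Adults in ICU with severe H1N1 influenza	Spain	Within 48 h of admission to ICU
GSE33341	validation	49	2	Adults with 2+ SIRS criteria and bacteremia	USA	Within 24 h of admission to hospital
GSE54514	validation	26	9	Adults in ICU with sepsis	Australia	Admission to ICU
GSE63990	validation	64	6	Adults with bacterial infection plus 2+ SIRS criteria	USA	Admission to ED
E-MTAB-4421.51	validation	15	7	Adults with sepsis (GAinS study)	UK	Day of hospital admission
Duke-HAI	hai	60	10	Adults who developed ventilator-associated pneumonia (VAP)	USA	Hospital days 1-30
GlueGrant-Burns	hai	84	8	Adults with severe burns (whole blood)	USA	Hospital days 1-30
GlueGrant-Trauma	hai	48	1	Adults with severe traumatic injuries (buffy coat)	USA	Hospital days 1-30
UF-P50-12H	hai	66	5	Adults with hospital-acquired sepsis	USA	Hospital days 1-30
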