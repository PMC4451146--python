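id	sex	father_id	mother_id	birth_year	death_year	emigration_year	parish	social_class	twin	first_born	married	marriage_year	n_children	maternal_age_at_birth
P1	male	F	M	1850	1912	NA	parish1	middle	0	1	1	1874	6	23
F	male	FF	FM	1825	1880	NA	parish1	middle	0	0	1	1848	1	28
M	female	MF	MM	1827	1885	NA	parish1	middle	0	1	1	1848	1	33
FF	male	FFF	FFM	1795	1851	NA	parish1	middle	0	0	1	1820	1	38
FM	female	FMF	FMM	1797	1860	NA	parish1	middle	0	0	1	1820	1	38
MF	male	MFF	MFM	1792	1844	NA	parish1	rich	0	1	1	1818	1	38
MM	female	MMF	MMM	1794	1852	NA	parish1	rich	0	0	1	1818	1	38
FFF	male	NA	NA	1755	1808	NA	parish1	middle	0	0	1	1780	1	NA
FFM	female	NA	NA	1757	1812	NA	parish1	middle	0	0	1	1780	1	NA
FMF	male	NA	NA	1757	1815	NA	parish1	poor	0	0	1	1781	1	NA
FMM	female	NA	NA	1759	1820	NA	parish1	poor	0	0	1	1781	1	NA
MFF	male	NA	NA	1752	1800	NA	parish1	rich	0	0	1	1778	1	NA
MFM	female	NA	NA	1754	1809	NA	parish1	rich	0	0	1	1778	1	NA
MMF	male	NA	NA	1754	1811	NA	parish1	rich	0	0	1	1779	1	NA
MMM	female	NA	NA	1756	1815	NA	parish1	rich	0	0	1	1779	1	NA
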