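# 15q11-q13 inversion status in human and nonhuman primates.
# Coordinates: T2T CHM13v2.0/hs1 chr15, 1-based inclusive (UCSC style).
# Genotypes: dir = direct orientation, inv = inverted orientation,
# n.a. = not assessable (region interrupted by a Pan-specific inversion).
# evolution: named ancestral branch on which the inversion arose.
region	chrom	start	end	HSA	PTR	GGO	PPY	MMU	CJA	evolution
BP1-BP2	chr15	20454276	21173858	dir/dir	dir/dir	dir/dir	inv/inv	inv/inv	inv/inv	African great ape ancestor
BP2-BP3	chr15	21173858	25860219	dir/inv	dir/dir	dir/dir	inv/inv	inv/inv	inv/inv	African great ape ancestor
BP3-BP5	chr15	26608046	29923396	dir/dir	n.a.	dir/dir	dir/dir	inv/inv	inv/inv	great apes ancestor
BP3-BP4	chr15	26617330	27847082	dir/dir	inv/inv	dir/inv	inv/inv	dir/dir	dir/dir	great apes ancestor
BP4-BP5	chr15	28677026	29923396	dir/inv	dir/dir	inv/inv	dir/dir	dir/dir	inv/inv	Catarrhini ancestor
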