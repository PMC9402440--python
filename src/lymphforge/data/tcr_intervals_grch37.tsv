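locus	chrom	start	end
TRA	chr14	22090057	23021075
TRB	chr7	141998851	142510972
TRG	chr7	38279625	38407656
TRD	chr14	22891537	22935569
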