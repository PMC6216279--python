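gene_id	start	end	strand	transl_table
MT-ND1	3308	4263	+	2
MT-ND2	4471	5512	+	2
MT-CO1	5905	7446	+	2
MT-CO2	7587	8270	+	2
MT-ATP8	8367	8573	+	2
MT-ATP6	8528	9208	+	2
MT-CO3	9208	9991	+	2
MT-ND3	10060	10405	+	2
MT-ND4L	10471	10767	+	2
MT-ND4	10761	12138	+	2
MT-ND5	12338	14149	+	2
MT-ND6	14150	14674	-	2
MT-CYB	14748	15888	+	2
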