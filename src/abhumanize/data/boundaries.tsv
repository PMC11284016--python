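scheme	chain_type	region	start	end
imgt	heavy	FR1	1	26
imgt	heavy	CDR1	27	38
imgt	heavy	FR2	39	55
imgt	heavy	CDR2	56	65
imgt	heavy	FR3	66	104
imgt	heavy	CDR3	105	117
imgt	heavy	FR4	118	128
imgt	kappa	FR1	1	26
imgt	kappa	CDR1	27	38
imgt	kappa	FR2	39	55
imgt	kappa	CDR2	56	65
imgt	kappa	FR3	66	104
imgt	kappa	CDR3	105	117
imgt	kappa	FR4	118	128
kabat	heavy	FR1	1	30
kabat	heavy	CDR1	31	35
kabat	heavy	FR2	36	49
kabat	heavy	CDR2	50	66
kabat	heavy	FR3	67	98
kabat	heavy	CDR3	99	105
kabat	heavy	FR4	106	116
kabat	kappa	FR1	1	23
kabat	kappa	CDR1	24	35
kabat	kappa	FR2	36	50
kabat	kappa	CDR2	51	57
kabat	kappa	FR3	58	89
kabat	kappa	CDR3	90	98
kabat	kappa	FR4	99	108
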