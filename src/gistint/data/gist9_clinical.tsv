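sample	location	genotype	risk	recurrence_status
01	gastric	wild_type	low	primary
02	gastric	wild_type	low	primary
03	gastric	KIT_mutant	high	primary
04	gastric	KIT_mutant	high	primary
05	gastric	KIT_mutant	low	primary
07	small_intestine	KIT_mutant	high	primary
08	small_intestine	KIT_mutant	high	recurrent
09	small_intestine	KIT_mutant	high	primary
10	small_intestine	KIT_mutant	high	primary
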