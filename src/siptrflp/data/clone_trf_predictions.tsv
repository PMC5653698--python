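sequence_id	enzyme	expected_length_bp	annotation
AE/AE-13D-05-001	HhaI	341	Hyphomicrobium sp. NDB2Meth4 (KY621474) (99)
AE/AE-13D-05-001	MspI	403	Hyphomicrobium sp. NDB2Meth4 (KY621474) (99)
AE/AE-13B-07-011	HhaI	355	Propioniferax sp. P7 (EU109728) (99)
AE/AE-13B-07-011	MspI	158	Propioniferax sp. P7 (EU109728) (99)
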