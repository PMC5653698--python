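condition,enzyme,length_bp
AE/AE-13D,HhaI,337
AE/AE-13D,MspI,398
AE/AE-13B,HhaI,352
AE/AE-13B,MspI,154
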