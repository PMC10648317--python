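(CJA,(MMU,(PPY,(GGO,(HSA,PTR)'Pan-Homo ancestor')'African great ape ancestor')'great apes ancestor')'Catarrhini ancestor')root;
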