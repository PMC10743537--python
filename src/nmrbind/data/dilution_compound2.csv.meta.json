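{"compound_id": "2", "buffer": "D2O, 25 mM NaCl / 25 mM K3PO4", "temperature_C": 10, "pH": 6.0}
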