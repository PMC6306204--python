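# Organelle stage ships with no built-in classes; users register LOCAL terms.
stage: Organelle
classes: []
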