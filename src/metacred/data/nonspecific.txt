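biological_process
biological regulation
regulation of biological process
cellular process
metabolic process
cellular metabolic process
primary metabolic process
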