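{
 "top_genes.tsv": "12e00be1bdd3ca51b8659ab0957894dea1827a1bb05e1ea5df5afc3a2f0391f1",
 "pathways.tsv": "ad28169b9e6dcf58c2082ad6bc88551ab923b705998056d4d1b61f34afea36e9",
 "nonspecific.txt": "b2cb483c35da4354d5df5f592c6db9097cb6b014d3cad874be73df31d7789030"
}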