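14	106032614	107288051	IGH
2	89156874	90274235	IGK
22	22380474	23265085	IGL
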