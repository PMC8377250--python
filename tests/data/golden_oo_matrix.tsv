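	O1	O2	O3	O4	A
O1	0.000000	0.698413	0.055556	0.095238	0.150794
O2	0.432609	0.000000	0.477174	0.021739	0.068478
O3	0.097756	0.519231	0.000000	0.282051	0.100962
O4	0.155556	0.105556	0.527778	0.000000	0.211111
A	0.277778	0.166667	0.416667	0.138889	0.000000
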