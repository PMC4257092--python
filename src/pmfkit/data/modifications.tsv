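# Shipped modification deltas (Da). targets: residue letters and/or N-TERM / C-TERM, comma separated.
# mode is the default search mode; callers may override.
name	targets	mono_delta	avg_delta	mode
propionamide	C	71.037114	71.0779	VARIABLE
oxidation	M	15.994915	15.9994	VARIABLE
carbamidomethyl	C	57.021464	57.0513	VARIABLE
phospho	S,T,Y	79.966331	79.9799	VARIABLE
hexnac	S,T,N	203.079373	203.1925	VARIABLE
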