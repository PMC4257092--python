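# Reference registry. FASTA files are NOT bundled: populate this directory by
# running scripts/fetch_references.py on a machine with network access; that
# script also rewrites the mature_start/mature_end columns (1-based precursor
# coordinates of the mature chain) from the documented mature-chain lengths.
# Blank span = full length. eogt_cdna is a nucleotide sequence (cDNA).
id	accession	fasta_path	mature_start	mature_end
obp1	NP_998961	obp1.fasta
obp2	ENSSSCP00000028674	obp2.fasta
veg	S77587	veg.fasta
veg_rm	AAO18367.1	veg_rm.fasta
veg_vno	AAB34720.1	veg_vno.fasta
sal	P81608	sal.fasta
eogt_cdna	JX546149	eogt_cdna.fasta
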