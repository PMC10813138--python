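# Cleaning rules for unspecific drug names and food supplements.
# kind: name (exact canonical name) or atc_prefix (ATC group prefix).
kind	pattern	label
name	unknown	unspecific name
name	unspecific	unspecific name
name	herbal preparation	unspecific name
name	food supplement	food supplement
name	multivitamin	food supplement
atc_prefix	A11	vitamins
atc_prefix	A12	mineral supplements
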