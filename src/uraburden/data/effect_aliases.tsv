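# Annotation-tool effect labels mapped to the controlled vocabulary.
# alias	effect
stopgain	stopgain
stop_gain	stopgain
stop gained	stopgain
stopgain SNV	stopgain
frameshift_insertion	frameshift_insertion
frameshift insertion	frameshift_insertion
frameshift_deletion	frameshift_deletion
frameshift deletion	frameshift_deletion
nonframeshift_insertion	nonframeshift_insertion
nonframeshift insertion	nonframeshift_insertion
nonframeshift_deletion	nonframeshift_deletion
nonframeshift deletion	nonframeshift_deletion
splice_donor	splice_donor
splice donor	splice_donor
splice_donor_variant	splice_donor
splice_acceptor	splice_acceptor
splice acceptor	splice_acceptor
splice_acceptor_variant	splice_acceptor
missense	missense
missense_variant	missense
nonsynonymous SNV	missense
nonsynonymous_SNV	missense
synonymous	synonymous
synonymous SNV	synonymous
synonymous_SNV	synonymous
other	other
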