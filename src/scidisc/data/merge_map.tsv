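# leaf_code	merged_code
# PSI-MI interaction-detection leaves mapped to their vocabulary parents.
MI:0006	MI:0019
MI:0007	MI:0019
MI:0019	MI:0019
MI:0096	MI:0096
MI:0018	MI:0018
MI:0397	MI:0018
MI:0416	MI:0416
MI:0663	MI:0663
MI:0114	MI:0114
MI:0107	MI:0107
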