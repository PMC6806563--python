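chr1	1500	6	60	61
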