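incident,mean,dry_matter
500,360,100
250,180,100
110,80,100
500,160,1600
250,85,1300
110,50,400
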