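scheme,replicate,generation,mean_night_sleep
long,1,13,642.2
long,2,13,667.8
short,1,13,104.3
short,2,13,156.2
control,1,0,519.6
control,1,13,563.4
control,2,0,567.9
control,2,13,542.3
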