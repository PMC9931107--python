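true_emotion,joy,neutral,sadness,anger
joy,65,15,5,15
neutral,17.5,62.5,20,0
sadness,0,25,75,0
anger,0,0,0,100
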