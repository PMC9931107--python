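true_emotion,joy,neutral,sadness,anger
joy,55,25,10,10
neutral,10,75,15,0
sadness,0,20,80,0
anger,0,0,0,100
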