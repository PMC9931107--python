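true_emotion,joy,neutral,sadness,anger
joy,80,10,10,0
neutral,0,90,0,10
sadness,5,10,85,0
anger,5,5,5,85
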