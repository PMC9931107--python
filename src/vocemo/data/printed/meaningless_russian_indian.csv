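true_emotion,joy,neutral,sadness,anger
joy,70,25,0,5
neutral,10,48,42,0
sadness,0,12,88,0
anger,10,5,0,85
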