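true_emotion,joy,neutral,sadness,anger
joy,40,45,5,10
neutral,0,30,70,0
sadness,5,10,85,0
anger,0,3,0,97
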