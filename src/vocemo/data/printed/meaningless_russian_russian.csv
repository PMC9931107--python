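true_emotion,joy,neutral,sadness,anger
joy,98,2,0,0
neutral,5,65,30,0
sadness,0,15,85,0
anger,17,10,3,70
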