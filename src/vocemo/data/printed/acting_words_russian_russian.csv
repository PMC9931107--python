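true_emotion,joy,neutral,sadness,anger
joy,85,5,10,0
neutral,5,90,5,0
sadness,0,5,95,0
anger,0,3,10,87
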