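true_emotion,joy,neutral,sadness,anger
joy,90,5,5,0
neutral,3,80,17,0
sadness,0,13,87,0
anger,0,2,8,90
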