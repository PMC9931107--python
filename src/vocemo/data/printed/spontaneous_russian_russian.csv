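true_emotion,joy,neutral,sadness,anger
joy,60,36,3,1
neutral,9,84,6,1
sadness,5,45,44,6
anger,9,47,19,25
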