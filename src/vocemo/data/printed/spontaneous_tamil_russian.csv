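true_emotion,joy,neutral,sadness,anger
joy,42,35,8,15
neutral,11,72,10,7
sadness,7,31,58,4
anger,24,29,5,42
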