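true_emotion,joy,neutral,sadness,anger
joy,39,25,18,18
neutral,7,46,31,16
sadness,13,31,36,20
anger,11,22,21,46
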