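true_emotion,joy,neutral,sadness,anger
joy,56,29,14,1
neutral,40,54,4,2
sadness,14,36,48,2
anger,7.5,7.5,0,85
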