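true_emotion,joy,neutral,sadness,anger
joy,80,17,2,1
neutral,6,86,6,2
sadness,1,9,86,4
anger,5,11,3,81
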