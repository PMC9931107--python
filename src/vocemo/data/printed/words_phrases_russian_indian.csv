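true_emotion,joy,neutral,sadness,anger
joy,50,38,2,10
neutral,2,40,58,0
sadness,2,28,70,0
anger,4,6,0,90
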