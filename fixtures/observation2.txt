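>A
-5 -4 1 2 3 6
>B
2 5 -4 -1 -3 6
>C
4 6 1 5 -3 2
>D
4 5 1 2 3 -6
>E
4 5 -6 3 1 2
>F
-5 -1 -6 3 4 2
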