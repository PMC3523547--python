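ddaf47a0c4fdf09117f0f1481998c22a0c8a35025e8beb913babbe3c7a24492d
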