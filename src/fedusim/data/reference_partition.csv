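client,total,normal,benign,malignant
1,3247,1250,1111,886
2,2541,714,1215,612
3,1823,408,720,695
4,2106,870,884,352
5,1652,747,671,234
6,847,260,325,262
7,1934,534,853,547
8,1697,609,738,350
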