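antigen,role,MP3C1,MP4A11,MP3B2,MP4F11,MP3G7,MP4G5,MP3A5,note
Heparin,reference_heparin,++,+,+,++,+,++,++,"segmentation of the printed eleven '+' characters across seven binders is ambiguous; all antibodies bind the reference heparin"
N-desulfated/N-acetylated heparin,n_desulfated,-,-,-,+,+,-,-,"constrained by results text: only MP4F11 and MP3G7 react with all desulfated heparins; MP4A11 does not bind the N-acetylated form"
2-O-desulfated heparin,o2_desulfated,-,+,-,++,+,-,-,"constrained by results text: MP4A11 detects the 2-O-desulfated form; MP4G5 and MP3A5 do not"
6-O-desulfated heparin,o6_desulfated,±,+,-,++,++,++,++,"constrained by results text: MP4G5 and MP3A5 detect the 6-O-desulfated form; residual 6-O sulfation remains in this preparation"
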