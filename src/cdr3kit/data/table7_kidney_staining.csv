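structure,MP3C1,MP4A11,MP3B2,MP4F11,MP3G7,MP4G5,MP3A5,HS4C3,note
Glomerular capillary tuft,++,-,++,++,±,+,++,++,"descriptive immunohistochemistry fixture; not parsed by the reactivity-panel reader (different level scale, includes ND)"
Glomerular mesangium,+,-,ND,+,+,+,±,+,"ND = no data"
Bowman's capsule,-,++,-,+,++,+,-,-,"constrained by results text: MP4A11 and MP3G7 primarily stain Bowman's capsule; MP4F11 and MP4G5 stain both capsule and glomerulus"
Peritubular capillaries,+,±,+,+,+,+,±,+,"segmentation unambiguous"
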