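antigen,role,MP3C1,MP4A11,MP3B2,MP4F11,MP3G7,MP4G5,MP3A5,MPB49,note
Heparin,reference_heparin,++,++,+++,++,++,++,+++,-,"segmentation of the printed '+' run across the seven binders is ambiguous; levels chosen to total the printed sixteen '+' characters, all binders moderate-or-stronger per the results text"
HS bovine kidney,heparan_sulfate,++,++,++,++,++,++,++,-,"unambiguous: fourteen '+' characters over seven binders, all described as moderate to strong"
HS intestinal mucosa,heparan_sulfate,-,+,±,++,+,++,±,-,"constrained by results text: MP4G5 and MP4F11 show strong binding to intestinal-mucosa HS"
Dermatan sulfate,other_gag,-,-,-,+,-,-,-,-,"constrained by results text: only MP4F11 shows moderate binding to dermatan sulfate"
Chondroitin sulfate A,other_gag,-,-,-,-,-,-,-,-,"unambiguous: no reactivity"
Chondroitin sulfate C,other_gag,-,-,-,-,-,-,-,-,"unambiguous: no reactivity"
DNA,dna,-,-,-,-,-,-,-,-,"unambiguous: no reactivity"
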