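phoneme_a,phoneme_b,phoneme_type,contrast_type
t,p,consonant,place-voiceless-plosive
t,k,consonant,place-voiceless-plosive
k,p,consonant,place-voiceless-plosive
f,θ,consonant,place-voiceless-fricative
f,s,consonant,place-voiceless-fricative
ʃ,s,consonant,place-voiceless-fricative
d,b,consonant,place-voiced-plosive
g,d,consonant,place-voiced-plosive
g,b,consonant,place-voiced-plosive
v,ð,consonant,place-voiced-fricative
v,z,consonant,place-voiced-fricative
ð,z,consonant,place-voiced-fricative
l,r,consonant,place-sonorant
j,l,consonant,place-sonorant
m,n,consonant,place-sonorant
z,s,consonant,voicing
ʒ,ʃ,consonant,voicing
θ,ð,consonant,voicing
t,s,consonant,manner
b,w,consonant,manner
tʃ,ʃ,consonant,manner
ð,b,consonant,manner+place
k,s,consonant,manner+place
g,r,consonant,manner+place
v,s,consonant,place+voicing
θ,z,consonant,place+voicing
m,v,consonant,place+voicing
ɪ,ɑː,vowel,monophthong
iː,æ,vowel,monophthong
ɔː,ɪ,vowel,monophthong
ʊ,ɑː,vowel,monophthong
uː,ʌ,vowel,monophthong
æ,e,vowel,monophthong
ʊ,ɪ,vowel,monophthong
æ,ɒ,vowel,monophthong
iː,uː,vowel,monophthong
ʌ,æ,vowel,monophthong
uː,ʊ,vowel,monophthong
iː,e,vowel,monophthong
ɔɪ,eɪ,vowel,diphthong
ɔɪ,aʊ,vowel,diphthong
aʊ,eɪ,vowel,diphthong
ɪə,əʊ,vowel,diphthong
ʊə,eɪ,vowel,diphthong
eə,ʊə,vowel,diphthong
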