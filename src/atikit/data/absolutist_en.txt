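# Absolutist dictionary, English (19 terms).
# Published absolutist-language word list (Al-Mosaiwi & Johnstone).
absolutely
all
always
complete
completely
constant
constantly
definitely
entire
ever
every
everyone
everything
full
must
never
nothing
totally
whole
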