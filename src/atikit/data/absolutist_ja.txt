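# Absolutist dictionary, Japanese translation (19 terms; synthetic stand-in
# translation list — opaque strings, no accent-variant expansion applies).
絶対に
すべて
いつも
完全
完全に
一定
常に
確実に
全体
決して
毎回
全員
全部
満杯
必ず
何も
全く
丸ごと
皆
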