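# Mental-health symptom comparison list, English (19 terms, as printed).
anxiety
depression
OCD
hopeless
angry
afraid
apathy
worthless
worried
restless
irritable
tense
scattered
tired
avoiding
procrastinate
insomnia
suicidal
suicide
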