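# Selective serotonin reuptake inhibitors: CANONICAL<TAB>SYNONYM
# Generic names plus major brand names; matching is whole-word,
# case-insensitive, punctuation-normalised.
fluoxetine	FLUOXETINE
fluoxetine	FLUOXETINE HYDROCHLORIDE
fluoxetine	PROZAC
fluoxetine	SARAFEM
citalopram	CITALOPRAM
citalopram	CITALOPRAM HYDROBROMIDE
citalopram	CELEXA
citalopram	CIPRAMIL
escitalopram	ESCITALOPRAM
escitalopram	ESCITALOPRAM OXALATE
escitalopram	LEXAPRO
escitalopram	CIPRALEX
paroxetine	PAROXETINE
paroxetine	PAROXETINE HYDROCHLORIDE
paroxetine	PAXIL
paroxetine	SEROXAT
paroxetine	BRISDELLE
sertraline	SERTRALINE
sertraline	SERTRALINE HYDROCHLORIDE
sertraline	ZOLOFT
sertraline	LUSTRAL
fluvoxamine	FLUVOXAMINE
fluvoxamine	FLUVOXAMINE MALEATE
fluvoxamine	LUVOX
fluvoxamine	FAVERIN
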