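accession	class
CHOP780201	alpha_turn_propensity
CHOP780203	alpha_turn_propensity
PALJ810101	alpha_turn_propensity
LEVM780101	alpha_turn_propensity
LEVM780103	alpha_turn_propensity
ISOY800101	alpha_turn_propensity
ISOY800103	alpha_turn_propensity
KANM800101	alpha_turn_propensity
ROBB760101	alpha_turn_propensity
CRAJ730101	alpha_turn_propensity
BURA740101	alpha_turn_propensity
NAGK730101	alpha_turn_propensity
GEIM800101	alpha_turn_propensity
PRAM900102	alpha_turn_propensity
CHOP780202	beta_propensity
LEVM780102	beta_propensity
ISOY800102	beta_propensity
KANM800102	beta_propensity
LIFS790101	beta_propensity
ROBB760105	beta_propensity
CRAJ730102	beta_propensity
NAGK730102	beta_propensity
GEIM800105	beta_propensity
PRAM900103	beta_propensity
KYTJ820101	hydrophobicity
HOPT810101	hydrophobicity
EISD840101	hydrophobicity
ZIMJ680101	hydrophobicity
PONP800101	hydrophobicity
ARGP820101	hydrophobicity
NOZY710101	hydrophobicity
MANP780101	hydrophobicity
SWER830101	hydrophobicity
FAUJ830101	hydrophobicity
CIDH920105	hydrophobicity
GRAR740101	composition
DAYM780101	composition
CEDJ970101	composition
CEDJ970102	composition
CEDJ970103	composition
JUKT750101	composition
ZIMJ680102	physicochemical
ZIMJ680104	physicochemical
GRAR740102	physicochemical
GRAR740103	physicochemical
BIGC670101	physicochemical
GOLD730102	physicochemical
DAWD720101	physicochemical
FAUJ880103	physicochemical
CHAM820101	physicochemical
MCMT640101	physicochemical
JANJ780101	other
CHOC760102	other
KARP850101	other
BHAR880101	other
VINM940101	other
JANJ790102	other
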