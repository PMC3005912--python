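>G1_A1
LMSYADTWFHVKGTGKPMCAVSTM
>G1_A2
LMSYADTWFHVKGTGKPMCAVSTMTHLSDHDLYDIK
>G1_B1
LMSYADTWFHVKGTGKPMCAVSTM
>G1_B2
LMSYADTWFHVKGTGKPMCAVSTMTHLSDHDLYDIK
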