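# Standard Gibbs free energies (and enthalpies) of formation at 25 degC,
# Thauer-style primed convention: aqueous species at 1 M, gases at 1 atm,
# water as the pure liquid, and the proton carrying the pH-7 correction
# (-39.87 kJ/mol) so that reaction sums give delta-G-zero-prime directly.
# Editable: rows may be added or values overridden for other compilations.
species	phase	dgf_kj_mol	dhf_kj_mol	carbon	hydrogen	oxygen	charge
acetate	aqueous	-369.41	-485.76	2	3	2	-1
water	water	-237.18	-285.83	0	2	1	0
methane	gas	-50.75	-74.81	1	4	0	0
bicarbonate	aqueous	-586.85	-691.99	1	1	3	-1
hydrogen	gas	0.0	0.0	0	2	0	0
proton	proton	-39.87	0.0	0	1	0	1
co2	gas	-394.36	-393.51	1	0	2	0
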