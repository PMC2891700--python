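# Attractive-minimum parameters for the 15 unordered CG site-type pairs.
# Columns: pair  r_min (Angstrom)  epsilon (kJ/mol)  repulsive_only (0/1)
# repulsive_only rows carry the shallow 0.1 kJ/mol well depth.
positive-negative	3.2	9.6	0
backbone-backbone	5.4	3.6	0
apolar-apolar	4.4	3.2	0
backbone-positive	4.8	2.4	0
backbone-polar	4.4	1.9	0
polar-polar	4.2	1.7	0
apolar-polar	4.4	1.6	0
backbone-apolar	4.8	1.4	0
polar-positive	4.0	1.1	0
backbone-negative	4.6	0.1	1
polar-negative	5.1	0.1	1
apolar-negative	5.8	0.1	1
apolar-positive	6.5	0.1	1
positive-positive	5.5	0.1	1
negative-negative	5.5	0.1	1
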