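label,condition,r_original,n_original,r_replication,n_replication,direction
pSPL -21 -63 61,Exact,-0.65,52,0.0130,37,-1
pSPL -21 -63 61,Sphere,-0.65,52,-0.220,37,-1
pSPL 34 -66 34,Exact,-0.60,52,-0.0875,37,-1
pSPL 34 -66 34,Sphere,-0.60,52,-0.196,37,-1
aSPL 42 -48 40,Exact,0.37,52,0.3856,37,1
aSPL 42 -48 40,Sphere,0.37,52,0.4644,37,1
GM mask peak 21 -58 66,Mask,,,0.4845,37,0
Occ GABA,Large,0.636,14,-0.0203,34,1
Occ GABA,Small,0.636,14,0.2304,15,1
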