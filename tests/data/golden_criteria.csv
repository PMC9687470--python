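# ba1_af_threshold=0.05
# bp4_mode=paper_complement
# brca2_terminal_codon_boundary=3326
# bs1_af_threshold=0.01
# clinvar_min_stars=2
# gerp_threshold=2.0
# lof_consequences=['frameshift', 'splice_acceptor', 'splice_donor', 'stop_gained', 'stop_lost']
# mmsplice_threshold=0.85
# ps4_or_threshold=2.0
# ps4_p_threshold=0.05
# splice_score_threshold=0.6
chrom,pos,ref,alt,PVS1,PS1,PS4,PM1,PM2,PM4,PM5,PP2,PP3,PP5,BA1,BS1,BP1,BP3,BP4,BP6,BP7,label
17,43045712,A,G,1,0,0,0,1,0,0,0,0,1,0,0,0,0,0,0,0,P/LP
13,32900001,G,-,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,VUS
17,41215000,C,T,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,1,0,B/LB
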