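chemical_class,drug,effect_class,n_testimonials,avg_duration_hours
Tryptamine,5-MeO-DMT,Psychedelic,282,0.2
Tryptamine,DMT,Psychedelic,531,0.2
Tryptamine,DPT,Psychedelic,148,3
Tryptamine,Psilocin,Psychedelic,597,4.5
Tryptamine,5-MeO-MiPT,Psychedelic,71,5
Tryptamine,5-MeO-DiPT,Psychedelic,208,6
Tryptamine,DiPT,Psychedelic,54,7
Tryptamine,5-MeO-TMT,Psychedelic,109,7.5
Phenethylamine,2C-D,Psychedelic,47,5
Phenethylamine,2C-B,Psychedelic,204,6
Phenethylamine,2C-C,Psychedelic,64,6
Phenethylamine,2C-T-2,Psychedelic,118,7
Phenethylamine,2C-P,Psychedelic,58,7.5
Phenethylamine,25I-NBOMe,Psychedelic,150,8
Phenethylamine,2C-I,Psychedelic,391,8
Phenethylamine,2C-E,Psychedelic,303,10
Phenethylamine,Mescaline,Psychedelic,136,11
Phenethylamine,2C-T-7,Psychedelic,173,11.5
Lysergamide,LSD,Psychedelic,1173,8.5
Diterpenoid,Salvinorin A,Dissociative hallucinogen,199,0.3
Arylcyclohexylamine,Ketamine,Dissociative anesthetic,405,1
Amphetamine,MDA,Entactogen,79,5
Amphetamine,MDMA,Entactogen,1155,5
Amphetamine,DOM,Psychedelic,36,17
Amphetamine,DOI,Psychedelic,34,23
Amphetamine,DOB,Psychedelic,45,24
Indole alkaloid,Ibogaine,Dissociative psychedelic,80,26
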