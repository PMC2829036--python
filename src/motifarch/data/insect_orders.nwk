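((Chelicerata,Crustacea)Outgroups,(Apterygota,(Paleoptera,(Polyneoptera,((Psocodea,(Thysanoptera,Heteroptera))Paraneoptera,(Hymenoptera,((Coleoptera,Neuropterida)Coleopterida,((Mecoptera,Diptera)Antliophora,(Trichoptera,Lepidoptera)Amphiesmenoptera)Panorpida)Aparaglossata)Holometabola)Eumetabola)Neoptera)Pterygota)Insecta)Arthropoda;
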