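# The 19 trusted monophyletic archaeal groups used for Slow-Fast site-rate
# estimation (classes/phyla whose monophyly is beyond dispute; Halobacteria
# deliberately uncovered because of their long stem).
# Member taxon ids below are SYNTHETIC placeholders (3 representatives each,
# pairwise disjoint): the real study taxa are only available as supplementary
# material, so this file documents the group structure, not real accessions.
DPANN_group_1_Diapherotrites: [diapherotrites_1, diapherotrites_2, diapherotrites_3]
DPANN_group_2_Aenigmarchaeota_Nanohaloarchaeota: [aenigmarchaeota_1, aenigmarchaeota_2, nanohaloarchaeota_1]
DPANN_group_3_Pacearchaeota_Woesearchaeota_Nanoarchaeota: [pacearchaeota_1, woesearchaeota_1, nanoarchaeota_1]
Stygia: [stygia_1, stygia_2, stygia_3]
Acherontia: [acherontia_1, acherontia_2, acherontia_3]
Crenarchaeota_group_1_Desulfurococcales: [desulfurococcales_1, desulfurococcales_2, desulfurococcales_3]
Crenarchaeota_group_2_Sulfolobales: [sulfolobales_1, sulfolobales_2, sulfolobales_3]
Crenarchaeota_group_3_Thermoproteales: [thermoproteales_1, thermoproteales_2, thermoproteales_3]
Crenarchaeota_group_4_Geoarchaeota: [geoarchaeota_1, geoarchaeota_2, geoarchaeota_3]
Verstraetearchaeota: [verstraetearchaeota_1, verstraetearchaeota_2, verstraetearchaeota_3]
Thaumarchaeota: [thaumarchaeota_1, thaumarchaeota_2, thaumarchaeota_3]
Aigarchaeota: [aigarchaeota_1, aigarchaeota_2, aigarchaeota_3]
Diaforarchaea: [diaforarchaea_1, diaforarchaea_2, diaforarchaea_3]
Methanomicrobia: [methanomicrobia_1, methanomicrobia_2, methanomicrobia_3]
Methanomada: [methanomada_1, methanomada_2, methanomada_3]
Archaeoglobi: [archaeoglobi_1, archaeoglobi_2, archaeoglobi_3]
Asgard: [asgard_1, asgard_2, asgard_3]
Bathyarchaeota: [bathyarchaeota_1, bathyarchaeota_2, bathyarchaeota_3]
Altiarchaea: [altiarchaea_1, altiarchaea_2, altiarchaea_3]
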