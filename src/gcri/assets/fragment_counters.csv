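name,provider
fr_Al_COO,rdkit.fragment
fr_Al_OH,rdkit.fragment
fr_Al_OH_noTert,rdkit.fragment
fr_ArN,rdkit.fragment
fr_Ar_COO,rdkit.fragment
fr_Ar_N,rdkit.fragment
fr_Ar_NH,rdkit.fragment
fr_Ar_OH,rdkit.fragment
fr_COO,rdkit.fragment
fr_COO2,rdkit.fragment
fr_C_O,rdkit.fragment
fr_C_O_noCOO,rdkit.fragment
fr_C_S,rdkit.fragment
fr_HOCCN,rdkit.fragment
fr_Imine,rdkit.fragment
fr_NH0,rdkit.fragment
fr_NH1,rdkit.fragment
fr_NH2,rdkit.fragment
fr_N_O,rdkit.fragment
fr_Ndealkylation1,rdkit.fragment
fr_Ndealkylation2,rdkit.fragment
fr_Nhpyrrole,rdkit.fragment
fr_SH,rdkit.fragment
fr_aldehyde,rdkit.fragment
fr_alkyl_carbamate,rdkit.fragment
fr_alkyl_halide,rdkit.fragment
fr_allylic_oxid,rdkit.fragment
fr_amide,rdkit.fragment
fr_amidine,rdkit.fragment
fr_aniline,rdkit.fragment
fr_aryl_methyl,rdkit.fragment
fr_azide,rdkit.fragment
fr_azo,rdkit.fragment
fr_barbitur,rdkit.fragment
fr_benzene,rdkit.fragment
fr_benzodiazepine,rdkit.fragment
fr_bicyclic,rdkit.fragment
fr_diazo,rdkit.fragment
fr_dihydropyridine,rdkit.fragment
fr_epoxide,rdkit.fragment
fr_ester,rdkit.fragment
fr_ether,rdkit.fragment
fr_furan,rdkit.fragment
fr_guanido,rdkit.fragment
fr_halogen,rdkit.fragment
fr_hdrzine,rdkit.fragment
fr_hdrzone,rdkit.fragment
fr_imidazole,rdkit.fragment
fr_imide,rdkit.fragment
fr_isocyan,rdkit.fragment
fr_isothiocyan,rdkit.fragment
fr_ketone,rdkit.fragment
fr_ketone_Topliss,rdkit.fragment
fr_lactam,rdkit.fragment
fr_lactone,rdkit.fragment
fr_methoxy,rdkit.fragment
fr_morpholine,rdkit.fragment
fr_nitrile,rdkit.fragment
fr_nitro,rdkit.fragment
fr_nitro_arom,rdkit.fragment
fr_nitro_arom_nonortho,rdkit.fragment
fr_nitroso,rdkit.fragment
fr_oxazole,rdkit.fragment
fr_oxime,rdkit.fragment
fr_para_hydroxylation,rdkit.fragment
fr_phenol,rdkit.fragment
fr_phenol_noOrthoHbond,rdkit.fragment
fr_phos_acid,rdkit.fragment
fr_phos_ester,rdkit.fragment
fr_piperdine,rdkit.fragment
fr_piperzine,rdkit.fragment
fr_priamide,rdkit.fragment
fr_pyridine,rdkit.fragment
fr_quatN,rdkit.fragment
fr_sulfide,rdkit.fragment
fr_sulfonamd,rdkit.fragment
fr_sulfone,rdkit.fragment
fr_term_acetylene,rdkit.fragment
fr_tetrazole,rdkit.fragment
fr_thiazole,rdkit.fragment
fr_thiocyan,rdkit.fragment
fr_thiophene,rdkit.fragment
fr_unbrch_alkane,rdkit.fragment
fr_urea,rdkit.fragment
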