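@prefix epo: <http://example.org/epo#> .
@prefix skos: <http://www.w3.org/2004/02/skos/core#> .

epo:adnexal_mass epo:definition "Inhomogeneous mass adjacent to, and moving separately from, the ovary." .
epo:adnexal_mass epo:kind "sign" .
epo:adnexal_mass epo:requires_view epo:left_adnexal_view .
epo:adnexal_mass epo:requires_view epo:right_adnexal_view .
epo:adnexal_mass epo:suggests epo:tubal_ectopic_pregnancy .
epo:adnexal_mass skos:prefLabel "Adnexal mass" .
epo:b_mode epo:kind "ultrasound_mode" .
epo:b_mode skos:prefLabel "B mode" .
epo:double_decidual_sac_sign epo:definition "Two concentric echogenic rings surrounding the gestational sac." .
epo:double_decidual_sac_sign epo:kind "sign" .
epo:double_decidual_sac_sign epo:requires_view epo:uterus_transverse_view .
epo:double_decidual_sac_sign epo:suggests epo:intrauterine_pregnancy .
epo:double_decidual_sac_sign skos:prefLabel "Double decidual sac sign" .
epo:embryo_with_cardiac_activity epo:definition "Embryonic pole with visible heartbeat." .
epo:embryo_with_cardiac_activity epo:kind "sign" .
epo:embryo_with_cardiac_activity epo:requires_view epo:uterus_sagittal_view .
epo:embryo_with_cardiac_activity epo:suggests epo:intrauterine_pregnancy .
epo:embryo_with_cardiac_activity skos:prefLabel "Embryo with cardiac activity" .
epo:empty_uterus epo:definition "No gestational sac visible within the endometrial cavity." .
epo:empty_uterus epo:kind "sign" .
epo:empty_uterus epo:requires_view epo:uterus_sagittal_view .
epo:empty_uterus epo:suggests epo:pregnancy_of_unknown_location .
epo:empty_uterus epo:suggests epo:tubal_ectopic_pregnancy .
epo:empty_uterus skos:prefLabel "Empty uterus" .
epo:endometrium epo:kind "anatomical_structure" .
epo:endometrium skos:prefLabel "Endometrium" .
epo:endometrium_zoom_view epo:kind "echographic_view" .
epo:endometrium_zoom_view skos:prefLabel "Zoomed view of the endometrium" .
epo:fallopian_tube epo:kind "anatomical_structure" .
epo:fallopian_tube skos:prefLabel "Fallopian tube" .
epo:free_pelvic_fluid epo:definition "Anechoic or echogenic fluid in the pouch of Douglas." .
epo:free_pelvic_fluid epo:kind "sign" .
epo:free_pelvic_fluid epo:requires_view epo:pouch_of_douglas_view .
epo:free_pelvic_fluid epo:suggests epo:tubal_ectopic_pregnancy .
epo:free_pelvic_fluid skos:prefLabel "Free pelvic fluid" .
epo:intrauterine_gestational_sac epo:definition "Anechoic fluid collection with echogenic rim within the endometrial cavity." .
epo:intrauterine_gestational_sac epo:kind "sign" .
epo:intrauterine_gestational_sac epo:located_in epo:uterus .
epo:intrauterine_gestational_sac epo:requires_view epo:uterus_sagittal_view .
epo:intrauterine_gestational_sac epo:suggests epo:intrauterine_pregnancy .
epo:intrauterine_gestational_sac skos:prefLabel "Intrauterine gestational sac" .
epo:intrauterine_pregnancy epo:definition "Pregnancy implanted within the endometrial cavity." .
epo:intrauterine_pregnancy epo:has_sign epo:double_decidual_sac_sign .
epo:intrauterine_pregnancy epo:has_sign epo:embryo_with_cardiac_activity .
epo:intrauterine_pregnancy epo:has_sign epo:intrauterine_gestational_sac .
epo:intrauterine_pregnancy epo:has_sign epo:yolk_sac .
epo:intrauterine_pregnancy epo:kind "disorder" .
epo:intrauterine_pregnancy skos:prefLabel "Intrauterine pregnancy" .
epo:left_adnexal_view epo:kind "echographic_view" .
epo:left_adnexal_view skos:prefLabel "Left adnexal view" .
epo:left_ovary epo:kind "anatomical_structure" .
epo:left_ovary skos:prefLabel "Left ovary" .
epo:pouch_of_douglas_view epo:kind "echographic_view" .
epo:pouch_of_douglas_view skos:prefLabel "Pouch of Douglas view" .
epo:pregnancy_of_unknown_location epo:definition "Positive pregnancy test with no pregnancy visualized on ultrasound." .
epo:pregnancy_of_unknown_location epo:has_sign epo:empty_uterus .
epo:pregnancy_of_unknown_location epo:has_sign epo:thin_endometrium .
epo:pregnancy_of_unknown_location epo:kind "disorder" .
epo:pregnancy_of_unknown_location skos:prefLabel "Pregnancy of unknown location" .
epo:pseudogestational_sac epo:definition "Intracavitary fluid without a decidual reaction, mimicking a sac." .
epo:pseudogestational_sac epo:kind "sign" .
epo:pseudogestational_sac epo:requires_view epo:uterus_sagittal_view .
epo:pseudogestational_sac epo:suggests epo:tubal_ectopic_pregnancy .
epo:pseudogestational_sac skos:prefLabel "Pseudogestational sac" .
epo:right_adnexal_view epo:kind "echographic_view" .
epo:right_adnexal_view skos:prefLabel "Right adnexal view" .
epo:right_ovary epo:kind "anatomical_structure" .
epo:right_ovary skos:prefLabel "Right ovary" .
epo:thin_endometrium epo:definition "Endometrial thickness below expectation for early pregnancy." .
epo:thin_endometrium epo:kind "sign" .
epo:thin_endometrium epo:located_in epo:endometrium .
epo:thin_endometrium epo:requires_view epo:endometrium_zoom_view .
epo:thin_endometrium epo:suggests epo:pregnancy_of_unknown_location .
epo:thin_endometrium skos:prefLabel "Thin endometrium" .
epo:transvaginal_route epo:kind "ultrasound_route" .
epo:transvaginal_route skos:prefLabel "Transvaginal route" .
epo:tubal_ectopic_pregnancy epo:definition "Pregnancy implanted in the fallopian tube." .
epo:tubal_ectopic_pregnancy epo:has_sign epo:adnexal_mass .
epo:tubal_ectopic_pregnancy epo:has_sign epo:empty_uterus .
epo:tubal_ectopic_pregnancy epo:has_sign epo:free_pelvic_fluid .
epo:tubal_ectopic_pregnancy epo:has_sign epo:pseudogestational_sac .
epo:tubal_ectopic_pregnancy epo:has_sign epo:tubal_ring_sign .
epo:tubal_ectopic_pregnancy epo:kind "disorder" .
epo:tubal_ectopic_pregnancy skos:prefLabel "Tubal ectopic pregnancy" .
epo:tubal_ring_sign epo:definition "Echogenic ring surrounding an extrauterine gestational sac." .
epo:tubal_ring_sign epo:kind "sign" .
epo:tubal_ring_sign epo:located_in epo:fallopian_tube .
epo:tubal_ring_sign epo:requires_view epo:left_adnexal_view .
epo:tubal_ring_sign epo:requires_view epo:right_adnexal_view .
epo:tubal_ring_sign epo:suggests epo:tubal_ectopic_pregnancy .
epo:tubal_ring_sign skos:prefLabel "Tubal ring sign" .
epo:uterus epo:kind "anatomical_structure" .
epo:uterus skos:prefLabel "Uterus" .
epo:uterus_sagittal_view epo:kind "echographic_view" .
epo:uterus_sagittal_view skos:prefLabel "Sagittal view of the uterus" .
epo:uterus_transverse_view epo:kind "echographic_view" .
epo:uterus_transverse_view skos:prefLabel "Transverse view of the uterus" .
epo:yolk_sac epo:definition "Thin-walled circular structure within the gestational sac." .
epo:yolk_sac epo:kind "sign" .
epo:yolk_sac epo:requires_view epo:endometrium_zoom_view .
epo:yolk_sac epo:suggests epo:intrauterine_pregnancy .
epo:yolk_sac skos:prefLabel "Yolk sac" .
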