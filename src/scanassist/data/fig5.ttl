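@prefix epo: <http://example.org/epo#> .
@prefix skos: <http://www.w3.org/2004/02/skos/core#> .

epo:disorder_1 epo:has_sign epo:sign_A .
epo:disorder_1 epo:has_sign epo:sign_B .
epo:disorder_1 epo:has_sign epo:sign_C .
epo:disorder_1 epo:kind "disorder" .
epo:disorder_1 skos:prefLabel "Disorder 1" .
epo:disorder_2 epo:has_sign epo:sign_A .
epo:disorder_2 epo:has_sign epo:sign_D .
epo:disorder_2 epo:kind "disorder" .
epo:disorder_2 skos:prefLabel "Disorder 2" .
epo:echographic_view_i epo:kind "echographic_view" .
epo:echographic_view_i skos:prefLabel "Echographic view i" .
epo:echographic_view_j epo:kind "echographic_view" .
epo:echographic_view_j skos:prefLabel "Echographic view j" .
epo:echographic_view_k epo:kind "echographic_view" .
epo:echographic_view_k skos:prefLabel "Echographic view k" .
epo:sign_A epo:kind "sign" .
epo:sign_A epo:requires_view epo:echographic_view_i .
epo:sign_A epo:suggests epo:disorder_1 .
epo:sign_A epo:suggests epo:disorder_2 .
epo:sign_A skos:prefLabel "Sign A" .
epo:sign_B epo:kind "sign" .
epo:sign_B epo:requires_view epo:echographic_view_j .
epo:sign_B epo:suggests epo:disorder_1 .
epo:sign_B skos:prefLabel "Sign B" .
epo:sign_C epo:kind "sign" .
epo:sign_C epo:requires_view epo:echographic_view_j .
epo:sign_C epo:suggests epo:disorder_1 .
epo:sign_C skos:prefLabel "Sign C" .
epo:sign_D epo:kind "sign" .
epo:sign_D epo:requires_view epo:echographic_view_k .
epo:sign_D epo:suggests epo:disorder_2 .
epo:sign_D skos:prefLabel "Sign D" .
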