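# Synthetic stand-in for the remote crowd-curated knowledge graph, used by
# the offline fixture endpoint.  It emulates the remote schema for the two
# federated query shapes (drug-gene interactions; variant response evidence
# with statement nodes and literature references).  Entity identifiers are
# invented except wd:Q14878377 (the PTEN gene item) and wd:Q38160427 (the
# Dabrafenib / Trametinib combination-therapy item).
@prefix wd:   <http://www.wikidata.org/entity/> .
@prefix wdt:  <http://www.wikidata.org/prop/direct/> .
@prefix p:    <http://www.wikidata.org/prop/> .
@prefix ps:   <http://www.wikidata.org/prop/statement/> .
@prefix prov: <http://www.w3.org/ns/prov#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

# ---- genes and their protein products (wdt:P688 = encodes) ----------------

wd:QG_BRAF  rdfs:label "BRAF" ;  wdt:P688 wd:QP_BRAF .
wd:QG_EGFR  rdfs:label "EGFR" ;  wdt:P688 wd:QP_EGFR .
wd:QG_ERBB2 rdfs:label "ERBB2" ; wdt:P688 wd:QP_ERBB2 .
wd:QG_KRAS  rdfs:label "KRAS" ;  wdt:P688 wd:QP_KRAS .
wd:Q14878377 rdfs:label "PTEN" ; wdt:P688 wd:QP_PTEN .

# ---- compounds physically interacting with products (wdt:P129) ------------

wd:QC_cetuximab   rdfs:label "cetuximab" ;   wdt:P129 wd:QP_EGFR .
wd:QC_gefitinib   rdfs:label "gefitinib" ;   wdt:P129 wd:QP_EGFR .
wd:QC_panitumumab rdfs:label "panitumumab" ; wdt:P129 wd:QP_EGFR .
wd:QC_trastuzumab rdfs:label "trastuzumab" ; wdt:P129 wd:QP_ERBB2 .
wd:QC_vemurafenib rdfs:label "vemurafenib" ; wdt:P129 wd:QP_BRAF .

# ---- variant response evidence --------------------------------------------
# p:P3354 / ps:P3354 = positive therapy predictor (statement + value)
# p:P3355 / ps:P3355 = negative therapy predictor

wd:Q38160427 rdfs:label "Dabrafenib / Trametinib combination therapy" .

wd:QV_BRAF_V600E rdfs:label "BRAF V600E" ;
    p:P3354 wd:QS_brafv600e_dabtram .
wd:QS_brafv600e_dabtram
    ps:P3354 wd:Q38160427 ;
    prov:wasDerivedFrom wd:QREF_melanoma_trial .
wd:QREF_melanoma_trial rdfs:label "combined BRAF and MEK inhibition trial" .

# contradictory evidence: the same variant predicts both a positive and a
# negative response to the same drug
wd:QV_KRAS_G13D rdfs:label "KRAS G13D" ;
    p:P3354 wd:QS_krasg13d_cet_pos ;
    p:P3355 wd:QS_krasg13d_cet_neg .
wd:QS_krasg13d_cet_pos
    ps:P3354 wd:QC_cetuximab ;
    prov:wasDerivedFrom wd:QREF_g13d_retrospective .
wd:QS_krasg13d_cet_neg
    ps:P3355 wd:QC_cetuximab ;
    prov:wasDerivedFrom wd:QREF_g13d_pooled .
wd:QREF_g13d_retrospective rdfs:label "retrospective G13D cetuximab analysis" .
wd:QREF_g13d_pooled rdfs:label "pooled G13D cetuximab analysis" .

# an unambiguously negative prediction for a mutated gene in the panel
wd:QV_KRAS_G12D rdfs:label "KRAS G12D" ;
    p:P3355 wd:QS_krasg12d_cet_neg .
wd:QS_krasg12d_cet_neg
    ps:P3355 wd:QC_cetuximab ;
    prov:wasDerivedFrom wd:QREF_ras_consensus .
wd:QREF_ras_consensus rdfs:label "RAS biomarker consensus statement" .
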