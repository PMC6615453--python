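@prefix : <http://example.org/lab/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix wd: <http://www.wikidata.org/entity/> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

:Aliquot rdf:type owl:Class ;
    rdfs:subClassOf :Bioentity .
:Alteration rdf:type owl:Class .
:Annotation rdf:type owl:Class .
:Bioentity rdf:type owl:Class .
:Case rdf:type owl:Class .
:CellLine rdf:type owl:Class ;
    rdfs:subClassOf :Bioentity .
:Chromosome rdf:type owl:Class .
:Copy_number_variation rdf:type owl:Class ;
    rdfs:subClassOf :Alteration .
:DNA rdf:type owl:Class ;
    rdfs:subClassOf :Bioentity .
:Drug_response rdf:type owl:Class .
:Exon rdf:type owl:Class ;
    rdfs:subClassOf :Region .
:Feature_amplification rdf:type owl:Class ;
    rdfs:subClassOf :Copy_number_variation .
:Gene rdf:type owl:Class ;
    rdfs:subClassOf :Region .
:Mouse rdf:type owl:Class ;
    rdfs:subClassOf :Bioentity .
:Peptide rdf:type owl:Class .
:RNA rdf:type owl:Class ;
    rdfs:subClassOf :Bioentity .
:Region rdf:type owl:Class .
:Response_type rdf:type owl:Class .
:Sequence_Alteration rdf:type owl:Class ;
    rdfs:subClassOf :Alteration .
:Tissue rdf:type owl:Class .
:Transcript rdf:type owl:Class .
:Treatment rdf:type owl:Class .
:ac rdf:type owl:DatatypeProperty .
:barcode rdf:type owl:DatatypeProperty .
:chrom_end rdf:type owl:DatatypeProperty .
:chrom_start rdf:type owl:DatatypeProperty .
:generates rdf:type owl:ObjectProperty ;
    rdfs:subPropertyOf :hasDescendant .
:hasDescendant rdf:type owl:ObjectProperty ;
    rdf:type owl:TransitiveProperty .
:has_annotation rdf:type owl:ObjectProperty .
:has_copy_number_variation rdf:type owl:ObjectProperty ;
    rdfs:subPropertyOf :has_variant .
:has_feature_amplification rdf:type owl:ObjectProperty ;
    rdfs:subPropertyOf :has_copy_number_variation .
:has_reference rdf:type owl:ObjectProperty .
:has_response_type rdf:type owl:ObjectProperty .
:has_sequence_alteration rdf:type owl:ObjectProperty ;
    rdfs:subPropertyOf :has_variant .
:has_treatment rdf:type owl:ObjectProperty .
:has_variant rdf:type owl:ObjectProperty .
:label rdf:type owl:DatatypeProperty .
:note rdf:type owl:DatatypeProperty .
:session rdf:type owl:DatatypeProperty .
:symbol rdf:type owl:DatatypeProperty .
:timestamp rdf:type owl:DatatypeProperty .
:user rdf:type owl:DatatypeProperty .
:volume_variation rdf:type owl:DatatypeProperty .
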