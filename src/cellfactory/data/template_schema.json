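{
  "name": "strain-design-template",
  "version": "1.0",
  "description": "45-field metabolic-engineering design template. Gene-parallel list fields are comma-joined inside a single delimited cell. Carbon-source blocks 2 and 3 are optional columns used when a fermentation fed more than one substrate; when absent their numeric features are encoded as zero.",
  "list_separator": ",",
  "categories": {
    "reactor_type": ["batch", "fed-batch", "continuous"],
    "oxygen": ["anaerobic", "microaerobic", "aerobic", "extra-aerobic"],
    "media": ["M9", "AM1", "AM2", "M9+YE", "LB", "NBS", "TB", "other rich media"]
  },
  "fields": [
    {"name": "record_id", "block": "meta", "type": "string", "required": false, "description": "stable row identifier"},
    {"name": "cs1", "block": "carbon_source", "type": "string", "required": true, "description": "first carbon source"},
    {"name": "cs1_mw", "block": "carbon_source", "type": "number", "unit": "g/mol", "description": "first carbon source molecular weight"},
    {"name": "cs_conc1", "block": "carbon_source", "type": "number", "unit": "mM", "description": "first carbon source concentration"},
    {"name": "CS_C1", "block": "carbon_source", "type": "number", "description": "mol C in first carbon source"},
    {"name": "CS_H1", "block": "carbon_source", "type": "number", "description": "mol H in first carbon source"},
    {"name": "CS_O1", "block": "carbon_source", "type": "number", "description": "mol O in first carbon source"},
    {"name": "reactor_type", "block": "bioprocess", "type": "category", "description": "continuous, batch or fed-batch (numeric codes 1/2/3 accepted)"},
    {"name": "rxt_volume", "block": "bioprocess", "type": "number", "unit": "L", "description": "working volume of reactor"},
    {"name": "media", "block": "bioprocess", "type": "category", "description": "fermentation media category; unrecognised strings map to 'other rich media'"},
    {"name": "temp", "block": "bioprocess", "type": "number", "unit": "degC", "description": "fermentation temperature"},
    {"name": "time", "block": "bioprocess", "type": "number", "unit": "h", "description": "total fermentation time"},
    {"name": "oxygen", "block": "bioprocess", "type": "category", "description": "aeration regime (numeric codes 1-4 accepted)"},
    {"name": "sbg_ref", "block": "genetic", "type": "string", "description": "reference (background) strain in the study"},
    {"name": "s_ref_gen", "block": "genetic", "type": "string_list", "description": "genes modified from MG1655 to obtain the background strain"},
    {"name": "s_gen_mod", "block": "genetic", "type": "flag_list", "description": "per background gene: 1 = insertion, 0 = deletion"},
    {"name": "gene_mod", "block": "genetic", "type": "string_list", "description": "genes modified from the study's reference strain"},
    {"name": "gene_del", "block": "genetic", "type": "flag_list", "description": "per gene: deleted?"},
    {"name": "gene_ovr", "block": "genetic", "type": "flag_list", "description": "per gene: overexpressed?"},
    {"name": "het_gene", "block": "genetic", "type": "flag_list", "description": "per gene: heterologous?"},
    {"name": "rep_origin", "block": "genetic", "type": "number_list", "description": "per gene: plasmid copy number"},
    {"name": "codon_opt", "block": "genetic", "type": "flag_list", "description": "per gene: codon optimised?"},
    {"name": "sen_reg", "block": "genetic", "type": "flag_list", "description": "per gene: sensor-regulator?"},
    {"name": "enz_design", "block": "genetic", "type": "flag_list", "description": "per gene: enzyme redesign/evolution?"},
    {"name": "protein_scaffold", "block": "genetic", "type": "flag_list", "description": "per gene: protein scaffolding?"},
    {"name": "dir_evo", "block": "genetic", "type": "flag", "description": "directed evolution used?"},
    {"name": "mod_path_opt", "block": "genetic", "type": "flag", "description": "modular pathway optimisation used?"},
    {"name": "prod_name", "block": "product", "type": "string", "description": "product name"},
    {"name": "no_C", "block": "product", "type": "number", "description": "mol C in product"},
    {"name": "no_H", "block": "product", "type": "number", "description": "mol H in product"},
    {"name": "no_O", "block": "product", "type": "number", "description": "mol O in product"},
    {"name": "no_N", "block": "product", "type": "number", "description": "mol N in product"},
    {"name": "mw", "block": "product", "type": "number", "unit": "g/mol", "description": "product molecular weight (derivable as 12C+1H+16O+14N)"},
    {"name": "precursor", "block": "product", "type": "category", "description": "central-metabolism precursor code"},
    {"name": "enz_steps", "block": "product", "type": "number", "description": "enzyme steps from precursor to product"},
    {"name": "atp_cost", "block": "product", "type": "number", "description": "ATP needed from precursor to product"},
    {"name": "na_cost", "block": "product", "type": "number", "description": "NADH/NADPH needed from precursor to product"},
    {"name": "yield_1", "block": "metrics", "type": "number", "unit": "g/g fed", "nullable": true, "description": "yield on carbon source fed"},
    {"name": "yield_2", "block": "metrics", "type": "number", "unit": "g/g consumed", "nullable": true, "description": "yield on carbon source consumed"},
    {"name": "yield_3", "block": "metrics", "type": "number", "unit": "g/g biomass", "nullable": true, "description": "yield on biomass"},
    {"name": "titer", "block": "metrics", "type": "number", "unit": "g/L", "nullable": true, "description": "product concentration"},
    {"name": "rate", "block": "metrics", "type": "number", "unit": "g/L/h", "nullable": true, "description": "maximum productivity"},
    {"name": "bio_titre", "block": "metrics", "type": "number", "unit": "g/L", "nullable": true, "description": "biomass concentration"},
    {"name": "bio_grw_rate", "block": "metrics", "type": "number", "unit": "1/h", "nullable": true, "description": "exponential-phase growth rate"},
    {"name": "gen_info", "block": "other", "type": "flag", "description": "all genetic modifications captured?"},
    {"name": "env_info", "block": "other", "type": "flag", "description": "all reactor conditions captured?"},
    {"name": "cs2", "block": "carbon_source_2", "type": "string", "required": false, "description": "second carbon source (optional block: cs2, cs2_mw, cs_conc2, CS_C2, CS_H2, CS_O2)"},
    {"name": "cs3", "block": "carbon_source_3", "type": "string", "required": false, "description": "third carbon source (optional block: cs3, cs3_mw, cs_conc3, CS_C3, CS_H3, CS_O3)"}
  ]
}
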