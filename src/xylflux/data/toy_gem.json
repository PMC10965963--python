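{
 "id": "toy_putida_core",
 "name": "Synthetic toy model for xylose-surgery and MFA-vs-FBA comparison tests (not a curated reconstruction)",
 "version": "1",
 "compartments": {"c": "cytosol", "p": "periplasm", "e": "extracellular"},
 "metabolites": [
  {"id": "glc__D_e", "name": "D-glucose", "compartment": "e", "formula": "C6H12O6", "charge": 0},
  {"id": "glcn_e", "name": "D-gluconate", "compartment": "e", "formula": "C6H12O7", "charge": 0},
  {"id": "xu5p__D_c", "name": "D-xylulose 5-phosphate", "compartment": "c", "formula": "C5H9O8P", "charge": 0},
  {"id": "pre_c", "name": "lumped biomass precursor", "compartment": "c", "formula": "C5H10O5", "charge": 0},
  {"id": "atp_c", "name": "ATP", "compartment": "c", "formula": "C10H12N5O13P3", "charge": 0},
  {"id": "adp_c", "name": "ADP", "compartment": "c", "formula": "C10H12N5O10P2", "charge": 0},
  {"id": "h_c", "name": "H+", "compartment": "c", "formula": "H", "charge": 1},
  {"id": "h_p", "name": "H+", "compartment": "p", "formula": "H", "charge": 1},
  {"id": "h_e", "name": "H+", "compartment": "e", "formula": "H", "charge": 1},
  {"id": "nad_c", "name": "NAD+", "compartment": "c", "formula": "C21H26N7O14P2", "charge": 0},
  {"id": "nadh_c", "name": "NADH", "compartment": "c", "formula": "C21H27N7O14P2", "charge": 0},
  {"id": "nadp_c", "name": "NADP+", "compartment": "c", "formula": "C21H25N7O17P3", "charge": 0},
  {"id": "nadph_c", "name": "NADPH", "compartment": "c", "formula": "C21H26N7O17P3", "charge": 0},
  {"id": "co2_c", "name": "CO2", "compartment": "c", "formula": "CO2", "charge": 0},
  {"id": "co2_e", "name": "CO2", "compartment": "e", "formula": "CO2", "charge": 0}
 ],
 "reactions": [
  {"id": "EX_glc__D_e", "name": "glucose exchange", "metabolites": {"glc__D_e": -1}, "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "EX_glcn_e", "name": "gluconate exchange", "metabolites": {"glcn_e": -1}, "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "GCD", "name": "periplasmic glucose dehydrogenase (lumped)", "metabolites": {"glc__D_e": -1, "glcn_e": 1}, "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "EFF", "name": "efficient precursor route", "metabolites": {"xu5p__D_c": -1, "atp_c": -1, "pre_c": 1, "adp_c": 1, "h_c": 1}, "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "BYPASS", "name": "decarboxylating NADPH bypass", "metabolites": {"xu5p__D_c": -1, "nadp_c": -1, "nadph_c": 1, "co2_c": 1, "pre_c": 0.8, "h_c": 1}, "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "CATAB", "name": "full oxidation", "metabolites": {"xu5p__D_c": -1, "nad_c": -3, "adp_c": -1, "nadh_c": 3, "co2_c": 5, "atp_c": 1}, "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "NOX", "name": "lumped respiration + oxidative phosphorylation", "metabolites": {"nadh_c": -1, "adp_c": -2, "nad_c": 1, "atp_c": 2}, "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "THD", "name": "transhydrogenase", "metabolites": {"nadph_c": -1, "nad_c": -1, "nadp_c": 1, "nadh_c": 1}, "lower_bound": -1000, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "BIOMASS_toy", "name": "biomass", "metabolites": {"pre_c": -1, "atp_c": -2, "nadph_c": -0.5, "adp_c": 2, "h_c": 2, "nadp_c": 0.5}, "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": "", "objective_coefficient": 1},
  {"id": "CO2t", "name": "CO2 diffusion", "metabolites": {"co2_c": -1, "co2_e": 1}, "lower_bound": -1000, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "EX_co2_e", "name": "CO2 exchange", "metabolites": {"co2_e": -1}, "lower_bound": -1000, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "Ht", "name": "proton leak c-p", "metabolites": {"h_c": -1, "h_p": 1}, "lower_bound": -1000, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "Hte", "name": "proton leak p-e", "metabolites": {"h_p": -1, "h_e": 1}, "lower_bound": -1000, "upper_bound": 1000, "gene_reaction_rule": ""},
  {"id": "EX_h_e", "name": "proton exchange", "metabolites": {"h_e": -1}, "lower_bound": -1000, "upper_bound": 1000, "gene_reaction_rule": ""}
 ],
 "genes": []
}
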