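{
    "compartments": {
        "c": "",
        "e": ""
    },
    "genes": [
        {
            "id": "b1817",
            "name": ""
        },
        {
            "id": "b1101",
            "name": ""
        },
        {
            "id": "b1818",
            "name": ""
        },
        {
            "id": "b1819",
            "name": ""
        },
        {
            "id": "b2417",
            "name": ""
        },
        {
            "id": "b2388",
            "name": ""
        },
        {
            "id": "b4025",
            "name": ""
        },
        {
            "id": "b3916",
            "name": ""
        },
        {
            "id": "b1723",
            "name": ""
        },
        {
            "id": "b2925",
            "name": ""
        },
        {
            "id": "b2097",
            "name": ""
        },
        {
            "id": "b3919",
            "name": ""
        },
        {
            "id": "b1779",
            "name": ""
        },
        {
            "id": "b2926",
            "name": ""
        },
        {
            "id": "b1676",
            "name": ""
        },
        {
            "id": "b1854",
            "name": ""
        }
    ],
    "id": "mini_ecoli_core",
    "metabolites": [
        {
            "compartment": "e",
            "id": "glc__D_e",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "glc__D_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "g6p_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "f6p_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "fdp_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "dhap_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "g3p_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "pep_c",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "pyr_c",
            "name": ""
        },
        {
            "compartment": "e",
            "id": "pyr_e",
            "name": ""
        }
    ],
    "reactions": [
        {
            "gene_reaction_rule": "",
            "id": "EX_glc__D_e",
            "lower_bound": -10,
            "metabolites": {
                "glc__D_e": -1
            },
            "name": "",
            "subsystem": "Exchange",
            "upper_bound": 0
        },
        {
            "gene_reaction_rule": "(b2417 and b1101) or (b1817 and b1818 and b1819)",
            "id": "GLCpts",
            "lower_bound": 0,
            "metabolites": {
                "glc__D_c": 1,
                "glc__D_e": -1,
                "pep_c": -1,
                "pyr_c": 1
            },
            "name": "",
            "subsystem": "Glycolysis/Gluconeogenesis",
            "upper_bound": 1000
        },
        {
            "gene_reaction_rule": "b2388",
            "id": "HEX1",
            "lower_bound": 0,
            "metabolites": {
                "g6p_c": 1,
                "glc__D_c": -1
            },
            "name": "",
            "subsystem": "Glycolysis/Gluconeogenesis",
            "upper_bound": 1000
        },
        {
            "gene_reaction_rule": "b4025",
            "id": "PGI",
            "lower_bound": -1000,
            "metabolites": {
                "f6p_c": 1,
                "g6p_c": -1
            },
            "name": "",
            "subsystem": "Glycolysis/Gluconeogenesis",
            "upper_bound": 1000
        },
        {
            "gene_reaction_rule": "b3916 or b1723",
            "id": "PFK",
            "lower_bound": 0,
            "metabolites": {
                "f6p_c": -1,
                "fdp_c": 1
            },
            "name": "",
            "subsystem": "Glycolysis/Gluconeogenesis",
            "upper_bound": 1000
        },
        {
            "gene_reaction_rule": "b2097 or b2925",
            "id": "FBA",
            "lower_bound": -1000,
            "metabolites": {
                "dhap_c": 1,
                "fdp_c": -1,
                "g3p_c": 1
            },
            "name": "",
            "subsystem": "Glycolysis/Gluconeogenesis",
            "upper_bound": 1000
        },
        {
            "gene_reaction_rule": "b3919",
            "id": "TPI",
            "lower_bound": -1000,
            "metabolites": {
                "dhap_c": -1,
                "g3p_c": 1
            },
            "name": "",
            "subsystem": "Glycolysis/Gluconeogenesis",
            "upper_bound": 1000
        },
        {
            "gene_reaction_rule": "b1779 and b2926",
            "id": "GLYC_LUMP",
            "lower_bound": 0,
            "metabolites": {
                "g3p_c": -1,
                "pep_c": 1
            },
            "name": "",
            "subsystem": "Glycolysis/Gluconeogenesis",
            "upper_bound": 1000
        },
        {
            "gene_reaction_rule": "b1854 or b1676",
            "id": "PYK",
            "lower_bound": 0,
            "metabolites": {
                "pep_c": -1,
                "pyr_c": 1
            },
            "name": "",
            "subsystem": "Glycolysis/Gluconeogenesis",
            "upper_bound": 1000
        },
        {
            "gene_reaction_rule": "",
            "id": "EX_pyr_e",
            "lower_bound": 0,
            "metabolites": {
                "pyr_c": -1
            },
            "name": "",
            "subsystem": "Exchange",
            "upper_bound": 1000
        }
    ],
    "version": "1"
}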