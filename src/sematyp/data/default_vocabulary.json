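{
 "entity_types": [
  "aapp",
  "acab",
  "acty",
  "aggp",
  "amas",
  "amph",
  "anab",
  "anim",
  "anst",
  "antb",
  "arch",
  "bacs",
  "bact",
  "bdsu",
  "bdsy",
  "bhvr",
  "biof",
  "bird",
  "blor",
  "bmod",
  "bodm",
  "bpoc",
  "bsoj",
  "carb",
  "celc",
  "celf",
  "cell",
  "cgab",
  "chem",
  "chvf",
  "chvs",
  "clas",
  "clna",
  "clnd",
  "cnce",
  "comd",
  "crbs",
  "diap",
  "dora",
  "drdd",
  "dsyn",
  "edac",
  "eehu",
  "eico",
  "elii",
  "emod",
  "emst",
  "enty",
  "enzy",
  "euka",
  "evnt",
  "famg",
  "ffas",
  "fish",
  "fndg",
  "fngs",
  "food",
  "ftcn",
  "genf",
  "geoa",
  "gngm",
  "gora",
  "grpa",
  "grup",
  "hcpp",
  "hcro",
  "hlca",
  "hops",
  "horm",
  "humn",
  "idcn",
  "imft",
  "inbe",
  "inch",
  "inpo",
  "inpr",
  "irda",
  "lang",
  "lbpr",
  "lbtr",
  "lipd",
  "mamm",
  "mbrt",
  "mcha",
  "medd",
  "menp",
  "mnob",
  "mobd",
  "moft",
  "mosq",
  "neop",
  "nnon",
  "npop",
  "nsba",
  "nusq",
  "ocac",
  "ocdi",
  "opco",
  "orch",
  "orga",
  "orgf",
  "orgm",
  "orgt",
  "ortf",
  "patf",
  "phob",
  "phpr",
  "phsf",
  "phsu",
  "plnt",
  "podg",
  "popg",
  "prog",
  "pros",
  "qlco",
  "qnco",
  "rcpt",
  "rept",
  "resa",
  "resd",
  "rnlw",
  "sbst",
  "shro",
  "socb",
  "sosy",
  "spco",
  "strd",
  "tisu",
  "tmco",
  "topp",
  "virs",
  "vita",
  "vtbt"
 ],
 "relation_types": [
  "ISA",
  "ASSOCIATED_WITH",
  "PHYSICALLY_RELATED_TO",
  "PART_OF",
  "CONSISTS_OF",
  "CONTAINS",
  "CONNECTED_TO",
  "INTERCONNECTS",
  "BRANCH_OF",
  "TRIBUTARY_OF",
  "INGREDIENT_OF",
  "SPATIALLY_RELATED_TO",
  "LOCATION_OF",
  "ADJACENT_TO",
  "SURROUNDS",
  "TRAVERSES",
  "FUNCTIONALLY_RELATED_TO",
  "AFFECTS",
  "MANAGES",
  "TREATS",
  "DISRUPTS",
  "COMPLICATES",
  "INTERACTS_WITH",
  "PREVENTS",
  "BRINGS_ABOUT",
  "PRODUCES",
  "CAUSES",
  "PERFORMS",
  "CARRIES_OUT",
  "EXHIBITS",
  "PRACTICES",
  "OCCURS_IN",
  "PROCESS_OF",
  "USES",
  "MANIFESTATION_OF",
  "INDICATES",
  "RESULT_OF",
  "TEMPORALLY_RELATED_TO",
  "CO-OCCURS_WITH",
  "PRECEDES",
  "CONCEPTUALLY_RELATED_TO",
  "EVALUATION_OF",
  "DEGREE_OF",
  "ANALYZES",
  "ASSESSES_EFFECT_OF",
  "MEASUREMENT_OF",
  "MEASURES",
  "DIAGNOSES",
  "PROPERTY_OF",
  "DERIVATIVE_OF",
  "DEVELOPMENTAL_FORM_OF",
  "METHOD_OF"
 ]
}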