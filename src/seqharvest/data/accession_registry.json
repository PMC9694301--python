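{
  "schema_version": 1,
  "comment": "Accession-identifier grammar. suffix_regex is anchored after the prefix; matching is case-insensitive with uppercase canonical form. 'extension' marks classes added for family symmetry beyond the documented prefix list.",
  "classes": [
    {"name": "BIOPROJECT",        "prefix": "PRJNA", "suffix_regex": "[0-9]{1,9}",   "suffix_rule": "1-9 decimal digits",            "level": "project",    "extension": false},
    {"name": "SRA_STUDY",         "prefix": "SRP",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "study",      "extension": false},
    {"name": "ENA_STUDY",         "prefix": "ERP",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "study",      "extension": false},
    {"name": "DDBJ_STUDY",        "prefix": "DRP",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "study",      "extension": false},
    {"name": "GEO_SERIES",        "prefix": "GSE",   "suffix_regex": "[0-9]{1,9}",   "suffix_rule": "1-9 decimal digits",            "level": "study",      "extension": false},
    {"name": "GEO_SAMPLE",        "prefix": "GSM",   "suffix_regex": "[0-9]{1,9}",   "suffix_rule": "1-9 decimal digits",            "level": "sample",     "extension": false},
    {"name": "SRA_RUN",           "prefix": "SRR",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "run",        "extension": false},
    {"name": "ENA_RUN",           "prefix": "ERR",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "run",        "extension": true},
    {"name": "DDBJ_RUN",          "prefix": "DRR",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "run",        "extension": false},
    {"name": "SRA_EXPERIMENT",    "prefix": "SRX",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "experiment", "extension": false},
    {"name": "ENA_EXPERIMENT",    "prefix": "ERX",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "experiment", "extension": false},
    {"name": "DDBJ_EXPERIMENT",   "prefix": "DRX",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "experiment", "extension": false},
    {"name": "SRA_SAMPLE",        "prefix": "SRS",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "sample",     "extension": false},
    {"name": "ENA_SAMPLE",        "prefix": "ERS",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "sample",     "extension": false},
    {"name": "DDBJ_SAMPLE",       "prefix": "DRS",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "sample",     "extension": false},
    {"name": "SRA_SUBMISSION",    "prefix": "SRA",   "suffix_regex": "[0-9]{5,9}",   "suffix_rule": "5-9 decimal digits",            "level": "submission", "extension": false},
    {"name": "BIOSAMPLE",         "prefix": "SAMN",  "suffix_regex": "[0-9]{1,12}",  "suffix_rule": "1-12 decimal digits",           "level": "sample",     "extension": false},
    {"name": "ENCODE_EXPERIMENT", "prefix": "ENCSR", "suffix_regex": "[0-9A-Z]{6}",  "suffix_rule": "exactly 6 uppercase alphanumerics", "level": "dataset", "extension": false},
    {"name": "ENCODE_BIOSAMPLE",  "prefix": "ENCSB", "suffix_regex": "[0-9A-Z]{6}",  "suffix_rule": "exactly 6 uppercase alphanumerics", "level": "sample",  "extension": false},
    {"name": "ENCODE_DATASET",    "prefix": "ENCSD", "suffix_regex": "[0-9A-Z]{6}",  "suffix_rule": "exactly 6 uppercase alphanumerics", "level": "dataset", "extension": false},
    {"name": "CXR",               "prefix": "CXR",   "suffix_regex": "[0-9]{1,9}",   "suffix_rule": "1-9 decimal digits",            "level": "dataset",    "extension": false}
  ]
}
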