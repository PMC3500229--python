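# Default code registry for the diabetes case-definition engine.
#
# Diagnosis codes are decimal-free ICD-9-CM prefixes (a dotted form like
# "250.0" is accepted and normalized).  A pattern matches any code extending
# it, except where the same set enumerates its own subcategories, in which
# case the shorter pattern is exact-only (see phenotyper.codesets).
#
# Procedure codes are CPT/HCPCS-style strings.  The named laboratory tests
# (glycosylated hemoglobin, glucose tolerance, quantitative glucose) carry
# their customary CPT codes here; every list can be overridden per site.

name: default

# Primary inpatient discharge diagnosis: diabetes without complication codes
# (the 250.4x-250.8x complication subcategories are deliberately absent, and
# the bare "250" entry is exact-only because its subcategories are listed).
dx_diabetes_primary_inpatient: ["250", "250.0", "250.1", "250.2", "250.3", "250.9"]

# Any diagnosis of diabetes: the whole 250 family.
dx_diabetes_general: ["250"]

# Polycystic ovarian syndrome (polycystic ovaries).
dx_pcos: ["256.4"]

# Absent / irregular menses families.
dx_menses_abnormal: ["626.0", "626.1", "626.4"]

# Drug classes come from the prescription table's closed vocabulary.
drug_insulin: ["insulin"]
drug_insulin_adjunct: ["insulin_adjunct"]
drug_oral_hypoglycemic: ["oral_hypoglycemic"]

# Procedures indicating diabetes management: glycosylated hemoglobin,
# glucose tolerance testing, quantitative glucose.
proc_glycosylated_hemoglobin: ["83036"]
proc_diabetes_management: ["83036", "82947", "82950", "82951"]

# Diabetes-related procedures eligible to reset the index date.
proc_diabetes_related: ["83036", "82947", "82950", "82951"]
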