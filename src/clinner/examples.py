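"""Worked-example generations from a real zero-shot run.

These are published mixtral-8x7b-instruct-v0.1 generations for one clinical
case (a renal hydatid disease report), one per prompt variation, together
with the document's silver-standard entities rendered in the keyed-list
format.  They exercise the characteristic output dialects: a free-text
numbered list (variation 1), a bracketed semicolon-delimited keyed list
wrapped in prose (variation 2), and a truncated JSON fragment with unquoted
keys and a non-canonical category (variation 3).
"""

MIXTRAL_VARIATION_1 = """\
1. Diseases:
- Fever
- Sub-Saharan origin (assumed geographical disease association)
- Eosinophilia
- Renal hydatid disease (also known as hydatid cyst or echinococcosis)
2. Symptoms:
- Sweating
- Fever
- Left lumbar pain
- Heaviness in the left flank
- Dysuria (painful urination)"""

MIXTRAL_VARIATION_2 = (
    "Here are the entities of types disease, symptom, and medical procedure "
    "identified in the clinical document:\n"
    "* Diseases: [renal hydatid disease;]\n"
    "* Symptoms: [sweating; fever; left lumbar pain; heaviness in the left "
    "flank; dysuria; occasional fever; voiding symptoms; acceptable urinary "
    "stream; night-time voiding once and daytime voiding every 3–4 hours "
    "with a feeling of complete emptiness]\n"
    "* Medical procedures: [physical examination; rectal examination; "
    "complementary tests; X-ray of the genito-urinary tract; renal "
    "ultrasound; abdominopelvic CT scan; echinococcus/hemag antibody "
    "serology; MRI; surgery; course of Albendazole; left nephroureterectomy] "
    "Note that some of the symptoms are mentioned more than once in the "
    "document, but I have only included each symptom once in the list. Also, "
    "some of the medical procedures are not specific to this case, and could "
    "be part of a general clinical workup, but I have included them for "
    "completeness."
)

MIXTRAL_VARIATION_3 = (
    "{ annotations:[ {entity: sub-Saharan origin, category: not applicable}, "
    "{entity:sweating and fever} ]"
)

SILVER_STANDARD_KEYED = (
    "{diseases: [lesions, cystic lesions, hydatid cyst, allergies, DM], "
    "symptoms: [colic, urinary stream, urgency, mass effect in the left "
    "flank, haematuria, Normal biochemistry, sweating, shortness of breath, "
    "eosinophilia, voiding symptoms, lumbar pain, occasional fever, normal "
    "haemogram, abdominal mass, Echinococcus/Hemag antibody serology was "
    "requested, which was POSITIVE, dribbling, feeling of complete "
    "emptiness, negative urine analysis, fever, asymptomatic, dysuria, "
    "heaviness in the left flank], medical procedures: [left flank on deep "
    "palpation, Renal ultrasound, Abdominopelvic CT scan, surgical "
    "treatment, complete left nephroureterectomy, MRI, Rectal examination, "
    "Physical examination, surgery]}"
)

#: item counts of the printed variation-2 lists
MIXTRAL_VARIATION_2_COUNTS = {"DISEASE": 1, "SYMPTOM": 9, "PROCEDURE": 11}
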