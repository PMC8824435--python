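"""Mock MedDRA-style terminology: system organ class (SOC) -> preferred terms.

A licensed MedDRA dictionary cannot be redistributed; this small bundled
map covers the 22 SOCs that occur in anticancer-drug ADR reporting and a
handful of preferred-term-like labels per SOC, enough to code synthetic
reports and to exercise the SOC tables and the signal-mining pipeline.
"""

from __future__ import annotations

# Ordered as the SOCs appear by descending overall report count.
SOC_TERMS: dict[str, tuple[str, ...]] = {
    "Gastrointestinal disorders": (
        "Nausea",
        "Vomiting",
        "Diarrhoea",
        "Abdominal pain",
    ),
    "Blood and lymphatic system disorders": (
        "Myelosuppression",
        "Leukopenia",
        "Anaemia",
        "Thrombocytopenia",
    ),
    "Skin and subcutaneous tissue disorders": (
        "Rash",
        "Urticaria",
        "Pruritus",
    ),
    "Investigations": (
        "Alanine aminotransferase increased",
        "Blood bilirubin increased",
    ),
    "General disorders and administration site conditions": (
        "Fever",
        "Chills",
        "Fatigue",
        "Infusion site reaction",
    ),
    "Nervous system disorders": (
        "Headache",
        "Dizziness",
        "Peripheral neuropathy",
    ),
    "Respiratory, thoracic, and mediastinal disorders": (
        "Dyspnea",
        "Pneumonitis",
        "Cough",
    ),
    "Vascular disorders": (
        "Hypertension",
        "Phlebitis",
        "Flushing",
    ),
    "Musculoskeletal and connective tissue disorders": (
        "Arthralgia",
        "Myalgia",
    ),
    "Cardiac disorders": (
        "Palpitations",
        "Chest discomfort",
        "Tachycardia",
    ),
    "Hepatobiliary disorders": (
        "Hepatic failure",
        "Hepatic function abnormal",
    ),
    "Metabolism and nutrition disorders": (
        "Decreased appetite",
        "Hypokalaemia",
    ),
    "Immune system disorders": (
        "Anaphylactoid reaction",
        "Hypersensitivity",
    ),
    "Renal and urinary disorders": (
        "Renal impairment",
        "Haematuria",
    ),
    "Endocrine disorders": (
        "Hyperthyroidism",
        "Hypothyroidism",
    ),
    "Psychiatric disorders": (
        "Insomnia",
        "Anxiety",
    ),
    "Eye disorders": (
        "Vision blurred",
        "Conjunctivitis",
    ),
    "Injury, poisoning, and procedural complications": (
        "Infusion related reaction",
        "Overdose",
    ),
    "Neoplasms benign, malignant, and unspecified (including cysts and polyps)": (
        "Haemangioma",
    ),
    "Ear and labyrinth disorders": (
        "Tinnitus",
        "Vertigo",
    ),
    "Infections and infestations": (
        "Pneumonia",
        "Upper respiratory tract infection",
    ),
    "Reproductive system and breast disorders": (
        "Menstrual disorder",
    ),
}

#: Reverse lookup, preferred term -> SOC.
TERM_SOC: dict[str, str] = {
    term: soc for soc, terms in SOC_TERMS.items() for term in terms
}


def soc_for_term(term: str) -> str:
    """Return the SOC a preferred term belongs to.

    Raises ``KeyError`` for terms absent from the bundled map.
    """
    return TERM_SOC[term]
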