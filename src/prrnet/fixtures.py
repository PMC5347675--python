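"""Published summary counts and gene lists used as packaged test inputs.

These are the printed marginal counts of the sex-stratified
finasteride-vs-minoxidil comparison (affected / total cases per event and
the overall gender composition) and the reproductive-toxicity gene-set
memberships highlighted by the enrichment analysis. They let every stage of
the pipeline be exercised and checked against published values without any
external database access: ``synthetic.fixture_from_counts`` reconstructs
report collections whose case-level counts reproduce these margins exactly.
"""

from __future__ import annotations

#: All-reports reference population: (male, female) report counts.
ALL_FAERS_SEX_COUNTS = (1_750_808, 2_818_346)

#: Gender composition of the alopecia case cohorts: drug -> (male, female).
COHORT_SEX_COUNTS = {
    "FINASTERIDE": (2076, 60),
    "MINOXIDIL": (92, 99),
}

#: Male stratum cohort totals (finasteride, minoxidil).
MALE_TOTALS = (2076, 92)
#: Female stratum cohort totals (finasteride, minoxidil).
FEMALE_TOTALS = (60, 99)

#: Male stratum: event -> (finasteride affected, minoxidil affected).
MALE_EVENT_COUNTS = {
    "ANXIETY": (671, 1),
    "CHORIORETINOPATHY": (3, 6),
    "COGNITIVE DISORDER": (607, 0),
    "DEPRESSION": (727, 3),
    "DERMATITIS CONTACT": (8, 6),
    "DIZZINESS": (67, 5),
    "EJACULATION DISORDER": (173, 1),
    "ERECTILE DYSFUNCTION": (1046, 4),
    "FATIGUE": (232, 2),
    "HEADACHE": (84, 6),
    "HYPOESTHESIA": (40, 4),
    "LIBIDO DECREASED": (496, 1),
    "LOSS OF LIBIDO": (305, 1),
    "SEMEN VOLUME DECREASED": (192, 1),
    "SEXUAL DYSFUNCTION": (956, 0),
    "SKIN DISORDER": (25, 3),
}

#: Female stratum: event -> (finasteride affected, minoxidil affected).
FEMALE_EVENT_COUNTS = {
    "ABORTION INDUCED": (11, 2),
    "ABORTION SPONTANEOUS": (8, 2),
    "ARTHRALGIA": (3, 9),
    "ARTHRITIS": (3, 0),
    "DERMATITIS CONTACT": (2, 9),
    "DIZZINESS": (2, 8),
    "ENDOMETRIAL HYPERTROPHY": (4, 0),
    "FATIGUE": (3, 5),
    "MENORRHAGIA": (4, 1),
    "MENSTRUATION IRREGULAR": (4, 1),
    "NAUSEA": (2, 7),
    "PALPITATIONS": (0, 8),
    "PATERNAL DRUGS AFFECTING FETUS": (5, 0),
    "PHALANGEAL AGENESIS": (3, 0),
    "PRURITUS": (1, 5),
    "SWELLING FACE": (0, 9),
    "TACHYCARDIA": (0, 6),
    "UTERINE CERVIX STENOSIS": (4, 0),
    "VISUAL ACUITY REDUCED": (0, 5),
    "WEIGHT INCREASED": (0, 5),
}

#: Published male finasteride top-10 ordering (most to least reported).
MALE_FINASTERIDE_TOP10 = (
    "ERECTILE DYSFUNCTION",
    "SEXUAL DYSFUNCTION",
    "DEPRESSION",
    "ANXIETY",
    "COGNITIVE DISORDER",
    "LIBIDO DECREASED",
    "LOSS OF LIBIDO",
    "FATIGUE",
    "SEMEN VOLUME DECREASED",
    "EJACULATION DISORDER",
)

#: Reproductive-toxicity gene sets (category id -> (name, members)).
REPRODUCTIVE_GENE_SETS = {
    "GO:0030518": (
        "Intracellular steroid hormone receptor signaling pathway",
        (
            "EP300", "PHB", "SMARCA4", "KAT5", "UBE2I", "SRC", "CCNE1",
            "PARK7", "TRIM68", "TADA3", "CALR", "PIAS1", "NR0B1", "RB1",
            "UBE3A", "NCOA6", "CTNNB1", "RNF4", "GRIP1", "MED24", "RAN",
            "MED1", "FKBP4", "NCOA2", "SIRT1", "SKP2", "FHL2", "BRCA1",
            "CDK7", "KDM3A", "NCOA3", "RNF6", "NCOA4", "DAXX", "PMEPA1",
            "PIAS2", "HDAC1", "AR", "NCOA1", "NR0B2", "RNF14", "FOXA1",
            "TGFB1I1",
        ),
    ),
    "GO:0030521": (
        "Androgen receptor signaling pathway",
        (
            "EP300", "PHB", "SMARCA4", "KAT5", "CCNE1", "PARK7", "TRIM68",
            "PIAS1", "RB1", "UBE3A", "CTNNB1", "RNF4", "MED24", "GRIP1",
            "RAN", "MED1", "FKBP4", "NCOA2", "SIRT1", "FHL2", "BRCA1",
            "CDK7", "KDM3A", "NCOA3", "RNF6", "NCOA4", "PMEPA1", "DAXX",
            "PIAS2", "HDAC1", "AR", "NR0B2", "NCOA1", "RNF14", "TGFB1I1",
        ),
    ),
    "hsa00140": (
        "Steroid hormone biosynthesis",
        ("AKR1D1", "CYP3A7", "CYP3A5", "AKR1C1", "SRD5A2", "AKR1C3",
         "SRD5A1", "CYP3A4"),
    ),
    "hsa04114": (
        "Oocyte meiosis",
        ("AR", "YWHAQ", "PPP1CA", "MAPK1", "PRKACA", "CCNE1", "CALM1"),
    ),
    "hsa04914": (
        "Progesterone-mediated oocyte maturation",
        ("HSP90AA1", "CDC25B", "AKT1", "MAPK1", "PRKACA", "RAF1"),
    ),
}
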