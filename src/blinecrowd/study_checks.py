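"""Arithmetic self-checks against the original contest's reported summaries.

The live B-line labeling contest this pipeline reimplements reported a set
of derived summary statistics (means, standard errors, percentages, rates)
alongside the raw counts and per-expert values they were computed from. The
raw inputs are embedded here as constants and every derived quantity is
recomputed with this package's own statistics code, giving a fast end-to-end
sanity check of the reporting arithmetic that needs no data download.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import summarize_expert_concordances

# --- reported raw inputs of the original contest -------------------------------

#: Per-expert correct counts on the 198 test clips vs the 6-expert consensus
#: reference — the unique integers consistent (to print rounding) with the
#: reported per-expert concordances 77.2, 81.3, 84.8, 87.3, 88.4, 90.9%.
EXPERT_CORRECT_COUNTS = (153, 161, 168, 173, 175, 180)
#: Per-expert correct counts vs their own leave-one-out reference — consistent
#: with the reported 75.8, 77.8, 79.8, 81.8, 83.3, 86.4%.
LOO_EXPERT_CORRECT_COUNTS = (150, 154, 158, 162, 165, 171)

EXPERT_CONCORDANCES = tuple(100.0 * k / 198 for k in EXPERT_CORRECT_COUNTS)
LOO_EXPERT_CONCORDANCES = tuple(100.0 * k / 198 for k in LOO_EXPERT_CORRECT_COUNTS)

N_TRAINING, N_TEST, N_UNLABELED = 195, 198, 1991
TEST_CLASS_COUNTS = {"no_blines": 138, "discrete": 36, "confluent": 24}
TRAIN_CLASS_COUNTS = {"no_blines": 114, "discrete": 56, "confluent": 25}

#: Crowd correct counts per reference class on the test set (consistent with
#: the reported per-class crowd concordances 99.3 / 50.0 / 79.2%).
CROWD_CORRECT_BY_CLASS = {"no_blines": 137, "discrete": 18, "confluent": 19}
#: Per-class mean expert concordances (%) vs the consensus reference.
EXPERT_CONCORDANCE_BY_CLASS = {"no_blines": 91.5, "discrete": 63.9, "confluent": 79.2}

N_OPINIONS_TOTAL = 99_238
N_USERS_TOTAL = 426
N_OPINIONS_ELIGIBLE = 34_363
N_USERS_ELIGIBLE = 114
N_OPINIONS_MEDICAL = 56_874
N_ELIGIBLE_OPINIONS_MEDICAL = 22_231
N_ELIGIBLE_USERS_MEDICAL = 60
N_USERS_MEDICAL = 190
CONTEST_HOURS = 138
EXPERT_HOURS_MEAN = 1.7
N_EXPERT_CLIPS = 393  # training + test clips each expert labeled

CROWD_CORRECT_TEST = 174  # test clips where the crowd label matched the reference
TRAIN_UNANIMOUS, TEST_UNANIMOUS = 98, 104
TRAIN_SUPERMAJORITY, TEST_SUPERMAJORITY = 174, 174
CROWD_SUPERMAJORITY = 170
DISCRETE_DISAGREEMENTS = 18  # crowd-vs-reference disagreements on discrete clips


@dataclass(frozen=True)
class CheckRow:
    name: str
    computed: float
    reported: float
    #: Half a unit of the reported value's last printed digit.
    precision: float = 0.05


def arithmetic_checks() -> list[CheckRow]:
    """Recompute every reported derived summary from its reported inputs."""
    full = summarize_expert_concordances(EXPERT_CONCORDANCES)
    loo = summarize_expert_concordances(LOO_EXPERT_CONCORDANCES)
    crowd_per_class = {
        cls: 100.0 * CROWD_CORRECT_BY_CLASS[cls] / TEST_CLASS_COUNTS[cls]
        for cls in TEST_CLASS_COUNTS
    }
    n_disagreements = N_TEST - CROWD_CORRECT_TEST
    rows = [
        CheckRow("expert_mean_concordance_pct", full.mean, 85.0),
        CheckRow("expert_concordance_se_pct", full.se, 2.0),
        CheckRow("loo_expert_mean_concordance_pct", loo.mean, 80.8),
        CheckRow("loo_expert_concordance_se_pct", loo.se, 1.6),
        CheckRow(
            "crowd_overall_concordance_pct", 100.0 * CROWD_CORRECT_TEST / N_TEST, 87.9
        ),
        CheckRow(
            "crowd_balanced_concordance_pct",
            sum(crowd_per_class.values()) / 3,
            76.1,
        ),
        CheckRow(
            "expert_balanced_concordance_pct",
            sum(EXPERT_CONCORDANCE_BY_CLASS.values()) / 3,
            78.2,
        ),
        CheckRow("total_clips", N_TRAINING + N_TEST + N_UNLABELED, 2384, 0.5),
        CheckRow(
            "test_no_blines_prevalence_pct",
            100.0 * TEST_CLASS_COUNTS["no_blines"] / N_TEST,
            70.0,
            0.5,
        ),
        CheckRow(
            "training_no_blines_prevalence_pct",
            100.0 * TRAIN_CLASS_COUNTS["no_blines"] / N_TRAINING,
            58.0,
            0.5,
        ),
        CheckRow(
            "crowd_opinions_per_minute",
            N_OPINIONS_TOTAL / (CONTEST_HOURS * 60),
            12.0,
        ),
        CheckRow(
            "expert_opinions_per_minute",
            N_EXPERT_CLIPS / (EXPERT_HOURS_MEAN * 60),
            3.9,
        ),
        CheckRow(
            "eligible_opinions_medical_pct",
            100.0 * N_ELIGIBLE_OPINIONS_MEDICAL / N_OPINIONS_ELIGIBLE,
            64.7,
        ),
        CheckRow(
            "all_opinions_medical_pct",
            100.0 * N_OPINIONS_MEDICAL / N_OPINIONS_TOTAL,
            57.3,
        ),
        CheckRow(
            "eligible_users_medical_pct",
            100.0 * N_ELIGIBLE_USERS_MEDICAL / N_USERS_ELIGIBLE,
            53.0,
            0.5,
        ),
        CheckRow(
            "all_users_medical_pct",
            100.0 * N_USERS_MEDICAL / N_USERS_TOTAL,
            45.0,
            0.5,
        ),
        CheckRow(
            "training_unanimous_pct", 100.0 * TRAIN_UNANIMOUS / N_TRAINING, 50.3
        ),
        CheckRow("test_unanimous_pct", 100.0 * TEST_UNANIMOUS / N_TEST, 52.5),
        CheckRow(
            "training_supermajority_pct",
            100.0 * TRAIN_SUPERMAJORITY / N_TRAINING,
            89.2,
        ),
        CheckRow(
            "test_supermajority_pct", 100.0 * TEST_SUPERMAJORITY / N_TEST, 87.9
        ),
        CheckRow(
            "crowd_supermajority_pct", 100.0 * CROWD_SUPERMAJORITY / N_TEST, 85.9
        ),
        CheckRow(
            "discrete_disagreement_share_pct",
            100.0 * DISCRETE_DISAGREEMENTS / n_disagreements,
            75.0,
            0.5,
        ),
    ]
    return rows
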