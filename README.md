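# blinecrowd

Label aggregation and evaluation for gamified crowdsourced annotation of
lung-ultrasound (POCUS) clips, where each clip is classified by B-line
severity into one of three ordinal classes: *no B-lines* < *discrete
B-lines* < *confluent B-lines*. B-lines are vertical hyperechoic artifacts
that mark pulmonary congestion; labeling them well normally takes trained
sonographers, which makes large labeled datasets expensive. The package
implements — and makes testable end-to-end without any clinical data — the
methodology by which a prize-driven labeling contest turns a general crowd
into an expert-level labeler:

* **Dynamic quality scoring.** Each user carries a quality score
  `Q = mean(last 50 correctness outcomes on feedback clips)`, zero until
  they have given 25 such opinions. A *feedback clip* is one whose label is
  known (an expert-labeled training clip, or an initially unlabeled clip
  already decided by the crowd) and is revealed to the user right after
  they answer. Opinions submitted while `Q < 0.80` are discarded.
* **Quality-filtered majority consensus with stopping rules.** On an
  unlabeled clip, each user's most recent eligible opinion counts once;
  the clip is decided when the top class leads the runner-up by ≥ 3 votes,
  or at 15 tallied opinions (majority, ties broken uniformly at random).
  A decided clip immediately becomes a feedback clip.
* **Reference standards.** Expert-labeled clips get the majority label of
  6 independent experts (ties random). A leave-one-out family of six
  5-expert standards scores each expert against a reference their own
  opinion did not influence, and scores the crowd as the mean fraction of
  the six standards it matches per clip.
* **Evaluation.** Overall / per-class / balanced concordance, paired
  *t* tests of per-case crowd-vs-expert concordance, one-vs-rest ROC of
  crowd vote fractions against the expert consensus, internal-agreement
  correlation (Pearson) and rank tests (Mann–Whitney U), Monte-Carlo
  opinion-subsampling ("how many opinions are enough?") and trailing-window
  learning curves.
* **Synthetic crowd simulator.** Because the original opinion log and clips
  are proprietary, a seeded generator emulates the study conditions: class
  priors 70/18/12, six experts spanning ≈ 0.77–0.91 accuracy, hundreds of
  users learning toward an ≈ 0.80 asymptote along
  `a(t) = a∞ − (a∞ − a0)·e^(−λt)`, severity-adjacent confusions, a shared
  clip-ambiguity effect, and the live contest loop with stratified feedback
  serving and on-the-fly promotion of decided clips.

## Worked example

Simulate a desk-scale contest (200 clips per split, 100 users, ~20k
opinions), then evaluate it:

```bash
$ blinecrowd simulate --seed 7 --outdir demo
wrote 20154 opinions to demo

$ blinecrowd evaluate --opinions demo/opinions.tsv \
    --manifest demo/clip_manifest.tsv --experts demo/expert_labels.tsv \
    --seed 7 --outdir demo/eval
crowd 89.5% vs expert mean 81.3% on 200 test clips
```

The quality-filtered, aggregated crowd (89.5% concordance with the 6-expert
consensus reference) beats the average individual simulated expert (81.3%)
even though every individual crowd labeler is configured to be weaker than
every expert — the wisdom-of-the-crowd effect the contest design is built
to exploit. `demo/eval/report.json` carries the full results (per-class and
balanced concordance, leave-one-out variants, paired tests, AUCs,
agreement statistics, skilled-user counts); curves are also written as TSV:

```bash
$ blinecrowd subsample --opinions demo/opinions.tsv \
    --manifest demo/clip_manifest.tsv --experts demo/expert_labels.tsv \
    --seed 7 --k-max 9 --outdir demo/sub
full-pool concordance 89.5%, knee at k=4
```

i.e. sampling just 4 eligible opinions per clip already comes within one
percentage point of the concordance of the full vote pools.

The same objects are available as a library:

```python
from blinecrowd import SimulationConfig, simulate_dataset, evaluate_contest

ds = simulate_dataset(SimulationConfig(rng_seed=7))
report = evaluate_contest(ds.opinions, ds.clips, ds.expert_table, seed=7)
print(report["crowd"]["overall_pct"], report["experts"]["mean_pct"])
```

`blinecrowd checks` recomputes, from the raw counts and per-expert values
the original contest reported, every derived summary statistic (means, SEs,
percentages, rates) and prints computed vs reported:

```
                           name  computed  reported
    expert_mean_concordance_pct    85.017      85.0
      expert_concordance_se_pct     2.044       2.0
loo_expert_mean_concordance_pct    80.808      80.8
  loo_expert_concordance_se_pct     1.570       1.6
  crowd_overall_concordance_pct    87.879      87.9
...
```

## Interchange formats

All inputs/outputs are tab-delimited text: an opinion log
(`user_id clip_id label event_index [qscore_at_submission eligible]`), a
clip manifest (`clip_id patient_id split [reference_label]`, extra columns
preserved), and an expert table (`clip_id` + one column per expert). Labels
are the canonical tokens `NO_BLINES` / `DISCRETE` / `CONFLUENT`. See
`docs/methods.md` for the model details, parameter choices and limitations.
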