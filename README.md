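# tickstats

Statistics for field surveys of two tick species (*Amblyomma variegatum*,
coded `Av`, and *A. hebraeum*, coded `Ah`) sharing cattle hosts: niche
overlap of attachment sites, co-occurrence null-model tests, sexual
isolation indices with bootstrap inference, beta-binomial regression of
con-specific mating, and herd-level detection probability — plus a seeded
synthetic-survey generator with the same hierarchical structure
(host → body region → <5 cm cluster → mating pair).

## Modules

| module                 | contents |
|------------------------|----------|
| `tickstats.survey`     | data model (`TickObservation`, `AnimalRecord`, `PresenceMatrix`, `MatingTable`, …), CSV I/O, acaricide-eligibility filter, abundance summaries, presence matrices, attachment distributions, mating tables |
| `tickstats.niche`      | Schoener's D between species (`D_H`) and across co-infestation status (`D_C`), by sex and host-infestation stratum |
| `tickstats.cooccur`    | normalised checkerboard C-score, permutation null models (`fixed_fixed` swap chain, `fixed_rows`, `equiprobable_rows`), two-sided Monte-Carlo tests |
| `tickstats.isolation`  | PSI / PTI / I_PSI / IA_PSI on 2×2 mating tables, 10,000-replicate bootstrap standard errors and two-tail probabilities |
| `tickstats.betabinom`  | beta-binomial logistic regression of con-specific mating proportions with within-host correlation ρ, likelihood-ratio tests, prediction surface (mean + CV) |
| `tickstats.detection`  | freedom-from-infestation detection probability per herd (binomial and finite-herd hypergeometric forms), high/low classification |
| `tickstats.simulate`   | mechanistic survey generator and direct beta-binomial draw generator, both fully seeded with truth records |
| `tickstats.cli`        | `tickstats` command with subcommands and JSON run manifests |

## CLI

All randomness flows from one `--seed`; subcommands derive independent
child streams, so outputs are reproducible and order-independent.  Every
run writes a `manifest_<subcommand>.json` recording inputs, outputs, seed
and package version.

```sh
tickstats simulate --seed 0 --out-dir out/            # survey.csv, animals.csv, truth.yaml
tickstats summarize out/survey.csv out/animals.csv --out-dir out/
tickstats overlap out/survey.csv --out-dir out/
tickstats cooccur out/survey.csv --level cluster --nperm 5000 \
    --null fixed_fixed --seed 1 --out-dir out/
tickstats isolation mating_table.csv --nboot 10000 --seed 1 --out-dir out/
tickstats mating-fit out/survey.csv --seed 1 --out-dir out/
tickstats detection samples.csv --out-dir out/
```

The survey CSV schema is one adult tick per row
(`site_id, animal_id, inspection_mode, species, sex, body_region,
cluster_id, partner_species`) with a `# tickstats-survey v1` header
comment; see `tickstats/survey.py` for details.  Mating tables use a long
CSV (`record_type, male_species, female_species, sex, count`) with `pair`,
`single` and optional `population` rows.

## Reporting convention for isolation indices

Summary estimates quote the *bootstrap mean* of each index alongside its
bootstrap standard error (matching the historical mate-choice software);
plug-in point estimates are always carried in the same result object. For
ratio-type indices (PSI, IA_PSI) the two differ slightly, which matters
when comparing 2-decimal published values.

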