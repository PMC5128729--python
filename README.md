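# medagg

A single-machine simulator and library for **dynamic, privacy-preserving
aggregation of clinical data from distributed sources**, aimed at people
studying federated research-data collection: health-informatics
researchers who want to model how medical institutions could pool patient
records for a study without a central registry, and anyone who needs a
reproducible testbed for negotiation-based data sharing protocols.

## The problem and the model

Collecting enough data for a clinical research question — say, building a
therapeutic-drug-monitoring (TDM) model of gentamicin dosing in neonates —
can take a single hospital years. If *n* institutions each accumulate *r*
eligible measurements per month, collecting *D* measurements locally takes

    t_loc = D / r            (months)

while pooling across *n* sites takes

    t_dist(n) = D / (n·r) + t_run(n)  ≈  t_loc / n

since the system's own run time `t_run` is seconds against months of data
collection. The hard part is not the arithmetic but the coordination, and
that is what this package simulates:

1. **Discovery** — nodes register at a publish/subscribe broker and
   advertise or request data by keyword sets (`medagg.broker`). A
   subscription matches a publication when its keywords are a subset of
   the publication's (case-insensitive).
2. **Negotiation** — the requesting node (*host*) opens a tuple centre
   (`medagg.tuplespace`, a Linda-style coordination space with reaction
   rules) and drives a state machine
   Started → Active → {Renegotiate, Failure, Success}
   (`medagg.negotiation`). The host's terms are a *study condition*:
   keywords KW, m attribute ranges, a record count N, and a privacy
   parameter k. A peer J accepts host I's terms iff

       KW_I ⊆ KW_J  ∧  min_p^J ≤ min_p^I  ∧  max_p^J ≥ max_p^I  (p = 1..m)

   and then offers Ñ = its number of matching records; the host
   apportions N proportionally among the offers.
3. **Release** — before any record leaves a node it is pseudonymized
   (keyed HMAC digest, so the same patient contributed twice merges to
   one research identity), generalized to *k*-anonymity over binary
   interval hierarchies (every quasi-identifier combination shared by
   ≥ k records, bounding re-identification probability by 1/k), and
   signed (`medagg.privacy`); the host verifies and ingests into the
   research database and republishes its metadata (`medagg.aggregation`).

Since the underlying neonatal TDM collection is not publicly deposited,
`medagg.synthetic_data` generates a clinically plausible stand-in
(default 8922 complete records: body weight, gestational age, postnatal
age, gender, drug concentration) plus off-topic decoy datasets, all
deterministic per seed.

## Worked example

```python
from dataclasses import replace
from medagg import (GeneratorConfig, generate_gentamicin, load_condition_bank,
                    partition_dataset, build_rsdb)
from medagg.experiments import make_profiles

pool = generate_gentamicin(GeneratorConfig(seed=0))          # 8922 records
parts = partition_dataset(pool, 3, seed=1)                   # 3 institutions
profiles = make_profiles(parts)

cond = replace(load_condition_bank()[0], n_records=40, privacy_k=2)
keys = {p.agent_id: f"key-{p.agent_id}" for p in profiles}
rsdb, result = build_rsdb(profiles[0], profiles[1:], cond, "study-key", keys)

print(result.session.state.value)   # Success
print(result.answers)               # {'node1': 125, 'node2': 130, 'node0': 100}
print(dict(result.allocation.quotas))  # {'node1': 14, 'node2': 15, 'node0': 11}
print(len(rsdb))                    # 40
```

The host asked for 40 records of term neonates (body weight 2000–3000 g,
gestational age 38–42 weeks) at k = 2. Each node offered its full match
count (125 + 130 + 100 = 355 matches exist across the three partitions —
exactly the number a central query on the unsplit pool finds), the host
apportioned the 40 requested records proportionally among the offers, and
the assembled research database holds 40 pseudonymized, generalized,
signature-verified records. Because the requested N was obtained and every
invitee finished, the session ends in `Success`; with a shortfall it would
stay quiescently `Active`, waiting for new publishers to join.

The same flows are scriptable from the shell:

```bash
medagg generate --n 8922 --seed 0 --out ldb.csv
medagg timing --d 6000 --r 100 --n 10      # -> 60 months local, 6 distributed
medagg consistency --n-agents 10 --seed 1
medagg fairness --n-runs 200 --seed 1 --plot fairness.png
```

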