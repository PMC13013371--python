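"""Plan the annotation-scarcity simulation and enumerate pre-training jobs.

For an 85-video procedure: hold out 20% for testing once, then build five
nested labeled subsets per label fraction alpha. Also enumerates the nine
weak pre-training jobs implied by three targets and five scenarios.
"""

from weaksurg import enumerate_pretrain_jobs, make_split_plan

plan = make_split_plan([f"v{i:03d}" for i in range(85)], "slg", master_seed=0)
print(f"85 videos -> test {len(plan.test_ids)}, training pool {plan.n_train}")
print("labeled videos per alpha (identical across the 5 splits):")
for alpha in plan.alphas:
    sizes = {len(s.labeled[alpha]) for s in plan.seeds}
    print(f"  alpha={alpha:<5} -> {sizes.pop()} videos")

jobs = enumerate_pretrain_jobs(["slg", "hys", "cho"])
print(f"\n{len(jobs)} weak pre-training jobs for 3 target procedures:")
for job in jobs:
    tgt = job.target or "shared"
    print(f"  {job.scenario:<13} label={job.label_type:<6} "
          f"sources={','.join(job.source_procedures):<12} target={tgt}")

# 17/34/51/68 labeled videos across the alpha grid; the three pooled or
# donor scenarios train one shared model each, the two within-procedure
# scenarios train one model per target: 3 + 3x2 = 9 pre-trained models.
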