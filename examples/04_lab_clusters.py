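"""Lab-value contrasts, group z-profiles, and cluster-break significance.

Per-patient medians are compared across three contrasts; significant labs
are z-profiled over the four sex-by-status groups and clustered with a
Monte-Carlo test of each dendrogram split (a significant break means the
two lab groups below it differ more than a single Gaussian explains).
"""

import emrpheno as ep

cfg = ep.default_config(n_patients=3000)
tables, truth = ep.generate_site(cfg, seed=4)

cases = ep.identify_cases(tables)
sex = dict(zip(tables.patients.patient_id, tables.patients.sex))
mat = ep.coverage_filter(ep.patient_medians(tables.labs))
compared = ep.compare_labs(mat, cases, sex)
sig = ep.significant_labs(compared)
print(f"{mat.shape[1]} labs pass the 95% missingness filter; "
      f"{len(sig)} significant in at least one contrast: {sig}")

profile = ep.group_z(mat, sig, cases, sex)
print("\nz-profile of group means (rows sum to 0, sd 1):")
print(profile.round(2).to_string())

if len(profile) >= 3:
    _, breaks = ep.cluster_breaks(profile, n_sim=500, seed=4)
    for b in breaks:
        if b.tested:
            print(f"\nsplit {sorted(b.members_left)} | "
                  f"{sorted(b.members_right)}: cluster index "
                  f"{b.statistic:.3f}, p = {b.p:.3f} "
                  f"({'significant' if b.significant else 'not significant'} "
                  f"at FWER level {b.alpha_level:.3f})")
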