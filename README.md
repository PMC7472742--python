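# sdrmap

Tools for locating a sex-determining region (SDR) in a species with **no
sexual dimorphism** — the situation of many cultured teleosts, where
larvae cannot be sexed and only the genetics can say who is male. The
package implements the full inference chain as a tested, reusable
pipeline over plain TSV inputs:

1. **Parentage** — exclusion-principle testing of larvae against
   candidate parents on multi-allelic (microsatellite-style) markers: a
   candidate is rejected if no allele it carries can explain the
   offspring call (conditionally on a known dam in the trio case).
2. **Sex-group assignment without phenotypes** — parental haplotypes are
   phased over the SDR markers in a full-sib family, and larvae are
   split into two putative sex-groups by the paternal haplotype they
   inherited (XY reading), the maternal haplotype (ZW reading), or a
   size-preserving random permutation (negative control).
3. **SDR refinement** — individuals whose genotypes flip to the
   opposite sex's consensus over a run of adjacent markers mark
   crossovers; the margins of those runs, intersected across
   individuals and families, delimit the SDR interval.
4. **Expression enrichment** — sex-biased differential expression
   between the assigned groups, all-or-nothing "sex-specific" tagging,
   and per-linkage-group enrichment by relative abundance

   ```
   RA_i = DE_i * G_t / (DE_t * G_i)
   ```

   where `DE_i` / `G_i` are the sex-biased-DE and total gene counts on
   linkage group *i* and `DE_t` / `G_t` the totals; `RA_i = 1` means no
   enrichment. A real SDR shows up as one linkage group with `RA_i`
   far above 1 under the true segregation scenario and nothing under
   the random control.
5. **Synthetic studies** — `sdrmap.simulate` generates families with
   planted crossovers, parentage panels, and negative-binomial count
   matrices with planted sex-biased genes, all with ground truth, so
   every stage is testable end to end without external data.

## Worked example

```python
import sdrmap as sm

cfg = sm.SimConfig()                       # the default synthetic study
table, phases, truth = sm.simulate_family(cfg, seed=1)

# phase the first family and assign larvae to putative sex-groups
phase = sm.phase_family(table, None, "F1")
groups = sm.assign_sex_groups(phase, "paternal",
                              sdr_interval=cfg.sdr_interval)

# expression: 16 larvae, planted sex-biased genes, enrichment per LG
keep = sorted(groups.groups)[:16]
assignment = sm.SexGroupAssignment(
    "paternal", {s: groups.groups[s] for s in keep},
    {s: groups.haplotypes[s] for s in keep})
ortho = sm.simulate_orthology(cfg, seed=3)
counts, ctruth = sm.simulate_counts(assignment, ortho, cfg, seed=4)

de = sm.test_de(counts, assignment, alpha=0.01)
sig = list(de.loc[de["significant"], "gene_id"])
summary = sm.enrichment_summary(sig, ortho)
print(len(sig), summary.argmax_lg(),
      round(summary.relative_abundance_of("tLG8"), 2),
      summary.percent_of("tLG8"))
```

prints

```
123 tLG8 9.54 41
```

— 123 genes called sex-biased at raw p < 0.01 (100 planted plus the
expected ~1% false positives), the sex-determining linkage group
`tLG8` attains the maximum relative abundance, with `RA = 9.54`
(9.5-fold over a uniform spread) and 41% of all sex-biased genes
landing on that one linkage group.

Every stage is also exposed on the command line (`sdrmap simulate`,
`validate`, `parentage`, `assign`, `refine`, `enrich`); run
`sdrmap <cmd> --help` for the options.

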