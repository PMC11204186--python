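# loopdist

Chromatin-compaction analysis of the human 15q12-q13.1 *HERC2/OCA2* region,
built around interphase-FISH inter-probe distance statistics.

The eye-color SNP rs12913832, in intron 86 of *HERC2*, modulates the
transcription of the neighboring *OCA2* gene through a chromatin loop. The
3 Mb region around the locus folds into three contiguous chromatin loops
(a, b, c — the smallest, c, holding only *HERC2*), and the degree of
compaction of this structure differs between cells carrying the A and G
alleles. `loopdist` provides a tested, reusable implementation of the
analyses that support this picture:

- **`loopdist.coords`** — genomic-interval arithmetic (1-based closed
  convention), the five-BAC probe panel, the three-loop annotation, BED I/O.
- **`loopdist.fish_sim`** — a synthetic-data generator emulating dual-color
  interphase FISH: genotype- and pair-specific 3D separations, uniformly
  random segment orientation in a spherical nucleus, two chromosome-15
  homologs, 2D projection, Gaussian localization noise.
- **`loopdist.estimator`** — the top-*k* distance statistic (mean of the 40
  largest of ≥200 projected distances) with pooled-variance Student's-t
  cross-condition comparisons and significance tiers.
- **`loopdist.contact_sim`** — a toy contact-matrix simulator (distance
  decay, within-loop enrichment, anchor corner peaks, Poisson depth noise)
  and an insulation-profile domain caller that recovers the three-loop
  structure.
- **`loopdist.synteny`** — conservation of gene order, orientation, and the
  *HERC2*→*OCA2* head-to-tail arrangement across vertebrate gene tables.

## The statistic

A FISH measurement records the 2D projection of a chromatin segment of true
3D length $d$. For uniformly random orientation the projection factor
$\rho = d_{2D}/d$ has density $\rho/\sqrt{1-\rho^2}$ on $(0,1)$, so the raw
mean underestimates $d$ by $\mathbb{E}[\rho] = \pi/4 \approx 0.785$. Ranking
the $n \ge 200$ measurements per condition and averaging the $k = 40$
largest selects near-in-plane segments:

$$\hat d = \frac{1}{k}\sum_{i=1}^{k} d_{2D}^{(i)}, \qquad
\mathbb{E}\!\left[\hat d\,/\,d\right] \to 0.9933 \ \ (k/n = 0.2),$$

recovering the true separation to within a percent in the noiseless limit.
Conditions (probe pair × rs12913832 genotype) are compared with two-sided
equal-variance Student's t-tests on the two top-40 subsets, with tiers
\* p<0.05, \*\* p<0.01, \*\*\* p<0.001, \*\*\*\* p<0.0001.

## Worked example

```sh
python examples/02_fish_cohort_topk.py
```

```
simulated 200 projected distances (one per nucleus)
raw mean:            1.784 um   (~ pi/4 * 2.2 = 1.728)
top-40-of-200 mean:  2.184 um   (true separation 2.2 um)
top-40 SD:           0.012 um

Monte-Carlo bias of the rule: top-40/200 mean recovers 99.29% (+/- 0.02%) of the true separation
```

The cohort is simulated at the calibrated AA-genotype separation for probe
pair #2-#3 (2.2 µm). The raw mean shows the π/4 projection bias; the top-40
mean recovers the configured separation to within 1%. The other examples
cover probe-panel arithmetic (`01`), the full 9-condition genotype
comparison (`03`), contact-map simulation and domain calling (`04`), and the
cross-species synteny report (`05`).

A thin CLI wraps the same calls:

```sh
loopdist compare --seed 7 --out out/          # cross-condition tables + strip plot
loopdist call-domains --out out/              # 3-domain TSV from the toy map
loopdist synteny-check --out out/             # cross-species conservation report
```

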