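# trflpkit

Analysis toolkit for characterizing bacterial communities in sediment
samples by **T-RFLP fingerprinting** (Terminal Restriction Fragment Length
Polymorphism) coupled with **in silico digestion of 16S rRNA clone
libraries**. It is written for microbial ecologists who have (a) sized
electropherogram peak tables from a capillary sequencer and (b) cloned 16S
sequences with taxonomic labels, and who want to know *which taxa produce
which fingerprint peaks* and *how diverse and how similar their communities
are*.

## What it computes

**In silico digestion.** Each clone is anchored at the labeled forward
primer (8F, `5'-AGA GTT TGA T(CT)(AC) TGG CTC AG-3'`, FAM-labeled) and
scanned 5'→3' for the first restriction site of each enzyme (BsuRI
`GG^CC`, RsaI `GT^AC`). The predicted terminal restriction fragment (T-RF)
length is the distance from the 5' primer base to the cut. Fragments
outside the 50–500 bp sizing window, clones without a locatable primer,
and clones without a site are flagged, never dropped.

**Peak attribution.** Predicted T-RFs seek their nearest observed peak
within a sizing tolerance (default ±1 bp); each peak's area is credited to
the taxonomic groups of its matched fragments, giving per-electropherogram
coverage percentages with exact conservation (attributed + unattributed =
100). Groups that share a fragment size are reported under a combined
label (e.g. `Epsilonproteobacteria+Flavobacteriia`).

**Chimera bookkeeping.** A window-based two-parent detector scans
candidate breakpoints: a clone is chimeric when assigning its flanks to
two different best-matching references improves identity by more than a
margin. Chimeras are cut at the breakpoint and both halves enter library
statistics as independent sequences.

**Diversity statistics.**

- Shannon entropy `H = -Σ pᵢ ln pᵢ` (nats), for OTU abundances and for
  binned fingerprint profiles;
- Chao1 richness `S_obs + n₁²/(2 n₂)` (bias-corrected form when `n₂ = 0`);
- Jukes–Cantor distances `D = -(3/4) ln(1 - 4p/3)` on pre-aligned
  sequences;
- furthest-neighbor (complete-linkage) OTU clustering at cutoffs
  0.01 / 0.03 / 0.05 and shared-OTU counts between libraries;
- homologous/heterologous coverage curves `C_X(D)`, `C_XY(D)` and the
  coverage-curve permutation test of library identity
  (`ΔC = Σ (C_X - C_XY)² ΔD`, label-shuffling null, Bonferroni threshold
  0.025 per direction);
- Bray–Curtis dissimilarity and nonmetric MDS (SMACOF, Kruskal stress-1)
  of the binned community matrix.

**Synthetic data.** A ground-truth generator emulates the whole study
design — a 30-taxon community with geometric rank abundances, two clone
libraries (101 and 93 clones with 11.9% / 4.3% chimera rates), and 5 sites
× 3 replicates of two-enzyme electropherograms with 0.3 bp sizing noise
and spurious low-level peaks — so every stage is testable against known
truth without any downloads.

## Worked example

```python
import trflpkit as tk

study = tk.default_study(seed=1)          # community + libraries + peaks
config = tk.RunConfig()

# predict T-RFs of the reference sequences
fragments = tk.digest_library(study["community"].references, config)

# attribute the BsuRI electropherogram of sample 1.1
profile = next(p for p in study["profiles"]
               if p.sample_id == "1.1" and p.enzyme == "BsuRI")
profile = tk.window_filter(profile, config.window)
atts = tk.match_fragments(
    [f for f in fragments if f.enzyme == "BsuRI"], profile,
    config.match_tolerance_bp)
report = tk.coverage_percentages(atts, profile, group_level="class")
for group, pct in sorted(report.percentages.items(), key=lambda kv: -kv[1]):
    print(f"{group:28s} {pct:5.1f}%")
print(f"{'unattributed':28s} {report.unattributed:5.1f}%")
```

prints

```
Gammaproteobacteria           29.3%
Epsilonproteobacteria         24.2%
Deltaproteobacteria           17.3%
Alphaproteobacteria           16.3%
Flavobacteriia                12.6%
unattributed                   0.4%
```

i.e. ~99.6% of this electropherogram's area is explained by the in silico
digest, with the small remainder from spurious peaks; the five class-level
percentages estimate the community composition of that sample.

The same stages are available from a shell:

```bash
trflpkit pipeline --seed 1 --out-dir run/
trflpkit compare run/library_1.2.fasta run/library_2.1.fasta \
    --seed 1 --out run/libshuff.json
```

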