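# endloop

How far apart are the two ends of an mRNA molecule?  In predicted secondary
structures the 5' and 3' termini are joined by the **exterior loop** — the
unpaired nucleotides enclosed by no base pair plus the closing pairs of the
outermost helices — and its backbone path length, the **contour length**

&nbsp;&nbsp;&nbsp;&nbsp;*C*<sub>L</sub> = *L* · *d*,&nbsp;&nbsp;
*L* = *u* + 2*h* − 1,&nbsp;&nbsp; *d* = 0.59 nm,

(*u* exterior unpaired nucleotides, *h* outermost helices) bounds the
end-to-end separation.  `endloop` is a toolkit for surveying C<sub>L</sub>
across mRNA cohorts: it filters full-length mRNA records (UTRs,
polyadenylation signal, poly(A) start, 200–7000 nt), folds them to
minimum-free-energy structures with ViennaRNA, measures the exterior loop,
and runs the comparison statistics — Gaussian histogram fits
(*A* e^(−(x−c)²/w²), so *w* = √2 σ and the one-sided 95% bound is
*c* + √2 *w*), a uniform-random-sequence null model, width rescaling with a
σ-confidence for the width excess, Welch tests, and Pearson/OLS
correlations of C<sub>L</sub> against GC content and 3'-UTR length.

It is written for computational RNA biologists who want to reproduce or
extend end-to-end-separation surveys on their own cohorts: the library
(`src/endloop/`) exposes every step, the numbered drivers under `analysis/`
run the standard analyses, and an `endloop` CLI covers the common cases.

## Worked example

The random-sequence null model — 50 sequences of 1600 nt, equal base
probabilities — is fully regenerable:

```sh
$ python analysis/01_random_control.py --seed 42
50 sequences of 1600 nt (seed 42): C_L in [1.77, 19.47] nm; Gaussian center
5.99 ± 0.64 nm, width w 3.95 ± 0.93 nm; 95% of molecules below 11.6 nm.
```

Each of the 50 contour lengths is one folded molecule's exterior loop in
nm; the Gaussian fit of their 2-nm histogram summarises the distribution —
its center is the typical end-to-end contour length of a random 1600-nt RNA
(≈ 10 links here; with only 50 molecules both fitted parameters move by a
few nm between seeds), and `center + √2·w` is the value 95% of molecules
stay below.

Derived quantities from published-scale fit parameters (native cohort:
center 9.0 ± 0.8 nm, width 6.03 nm; random control: 7.7 ± 0.4, 2.6 ± 0.7):

```sh
$ python analysis/03_width_excess.py
95% of native molecules lie below 17.5 nm, random ones below 11.4 nm.
Rescaling the random width to the native center gives 3.04 ± 0.88 nm; the
native width of 6.03 nm exceeds it by 3.4 sigma — too large to be a
statistical fluctuation.
```

The rescaled width is what the native distribution's width *would* be if it
were just the random-sequence spread shifted to the native center; the
σ-value says how many standard deviations the observed native width lies
above that expectation.

Structure-level stability of the statistic (`analysis/02_mfe_vs_suboptimal.py`)
folds each sequence's 5 lowest-energy alternative structures and confirms by
Welch test that C<sub>L</sub> does not depend on which near-optimal
structure the molecule adopts:

```sh
$ python analysis/02_mfe_vs_suboptimal.py --seed 42
N=20 sequences, k=5: mean suboptimal/MFE C_L ratio 0.994; Welch t=0.053,
dof=26.7, P=0.9585 -> no significant difference between MFE and suboptimal
contour lengths.
```

`analysis/04_survey_demo.py` runs the whole
survey (per-species mean ± SEM, pooled fit, group contrasts, correlations)
on a synthetic annotated cohort and writes the report tables.

## CLI

```sh
endloop survey --fasta cohort.fa --out report/        # filter→fold→measure→stats
endloop random-control --n 50 --len 1600 --seed 42
endloop compare-subopt --fasta seqs.fa --k 5
endloop compute --in structures.fold --out cl.tsv     # structures folded elsewhere
endloop filter --fasta cohort.fa --out filter.tsv
endloop gen --n 50 --len 1600 --seed 42 --out-fasta random.fa
```

Annotated FASTA headers carry cohort metadata
(`species=CR clade=viridiplantae gene_class=homologous utr5=1-50 cds=51-300 utr3=301-391`);
GenBank input takes the same information from the feature table.

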