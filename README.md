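# foldkit

Analysis toolkit for *in vitro* outer-membrane-protein (OMP) folding
studies: the quantitative pipeline that connects fluorescence folding
kinetics, chaperone-binding titrations, gel/CD observables, and
coarse-grained membrane simulations of how a folding catalyst such as
BamA perturbs the bilayer around its β-barrel seam.

It is written for experimentalists and simulators who measure OMP
folding into liposomes and want a tested, scriptable version of the
standard analysis steps, with seeded synthetic-data generators so every
stage can be validated without instrument or trajectory files.

## What it computes

**Kinetics** (`foldkit.kinetics`). Folding transients are fitted
globally to

&nbsp;&nbsp;&nbsp;&nbsp;*y(t) = A₁·e^(−k₁t) + c*  or
*y(t) = A₁·e^(−k₁t) + A₂·e^(−k₂t) + c*

with the rate constant(s) *k* shared across replicates and amplitudes
and offsets free per trace (variable-projection least squares with a
multistart rate grid). Lag-phase transients are summarized by *t₅₀* —
the time to reach halfway between the signal minimum and a horizontal
baseline fitted to the trailing part of the trace. Conditions are
compared by fold changes *R = X/Y* with errors propagated in quadrature,
*δR = |R|·√((δX/X)² + (δY/Y)²)*, where *δX*, *δY* are s.e.m. values
(computed between liposome batches when batch identifiers are present).

**Binding** (`foldkit.binding`). Titrations are fitted to the Hill
equation

&nbsp;&nbsp;&nbsp;&nbsp;*S_obs = S_U + (S_B − S_U)·Cⁿ / (K_D + Cⁿ)*

reporting both *K_D* (units of concentrationⁿ, as printed in the
equation) and the apparent dissociation constant
*K_d,app = K_D^(1/n)* — the half-saturation concentration, which is
what affinities are quoted in. The serial-dilution simulator reproduces
the 16-point two-fold design from a 100 μM top concentration (down to
~3 nM).

**Observables** (`foldkit.observables`). Fraction folded from cold
semi-native SDS-PAGE band intensities, and mean residue ellipticity
*[θ]_MRE = MRW·θ_λ/(10·d·c)* with *MRW = M/(N−1)* for CD spectra.

**Membrane** (`foldkit.membrane`). From MARTINI-style coarse-grained
frames (GRO files or the built-in generator): phosphate-based bilayer
thickness and per-bond order parameters *S = ½(3cos²θ − 1)* (bonds G-1,
1-2, 2-3, 3-4 as chain length allows), computed for annular lipids
within 12 Å of designated anchor residues (e.g. the barrel-seam residue
808 and its diametrically opposite residue 613), and for bulk lipid
farther than 30 Å from the protein — aggregated over post-burn-in
frames and reported as mean ± SD over replicas.

**Synthetic data** (`foldkit.synthetic`). Seeded generators for all of
the above, including a planar two-leaflet bilayer around a cylindrical
barrel with an analytically known thinning/disorder field, so recovery
tests are sharp.

## Worked example

```bash
python examples/03_hill_titration.py
```

```
titration: 16 points, 100 uM down to 3.1 nM
free n:  K_d,app = 1.78 uM, n = 1.53, RSS = 1.53e-03
n = 1:   K_d,app = 1.91 uM, RSS = 2.50e-02
```

A 16-point titration simulated from K_d,app = 1.8 μM, n = 1.5 with 1%
noise is refitted: the free-Hill-coefficient fit recovers both
parameters and has ~16× lower residuals than the non-cooperative n = 1
fit — the signature of multivalent binding. The other examples cover
the global kinetic fit (`01`), *t₅₀*/fold-change analysis (`02`), and
the seam-vs-bulk membrane profile (`04`), each printing the numbers it
computes and what they mean.

A thin CLI mirrors the library for shell use:

```bash
foldkit simulate transients --seed 3 --out tr.csv
foldkit fit-kinetics tr.csv --model auto
foldkit fit-hill titration.csv --fix-n 1
foldkit membrane-profile rep1.gro rep2.gro --anchor 808 --anchor 613
```

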