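# heraldspec

Simulation and coincidence analysis of heralded single-photon fluorescence
experiments: a Monte Carlo model of a pulsed pair source (thermal pair-number
statistics), lossy herald and fluorescence detection with exponential
emission delay and Gaussian instrument jitter, plus the full analysis chain —
cross-correlation / IRF-reconvolved lifetime fitting, gated three-detector
conditional g²(0), and the heralds-per-fluorescence counting distribution
with its geometric-law overlay.

## Layout

| module | purpose |
| --- | --- |
| `heraldspec.timetags` | time-tag stream data model, text I/O, per-channel rates |
| `heraldspec.models` | closed-form counting statistics: pair-number pmf, multi-photon weights, heralded g² estimate `2n_p/(1+n_p)`, geometric P(N) and its exponential-tail limit, geometric ML fitting |
| `heraldspec.simulator` | stochastic-trajectory Monte Carlo generator of detector tag streams |
| `heraldspec.correlator` | cross-correlation histograms, gated singles/coincidences, conditional g²(0) with Poisson errors, herald-count distribution |
| `heraldspec.lifetime` | IRF estimation from the herald–residue correlation; Poisson-MLE single-exponential reconvolution fit with profile-likelihood CIs |
| `heraldspec.pipeline` | seeded end-to-end reproductions of the three result sets |
| `heraldspec.cli` | `heraldspec` command-line entry point |

Time tags are 64-bit integer picoseconds; streams are stored as
tab-separated `channel<TAB>time` text with a `# key=value` JSON-encoded
metadata header, so files are inspectable and round-trip bit-exactly.

## CLI

```sh
# simulate a run (YAML config maps to ExperimentConfig fields)
heraldspec simulate --config cfg.yaml --seed 1 --out run.tags.tsv

# analyses on a stream file
heraldspec analyze xcorr run.tags.tsv --bin 128 --window 11776 --out xcorr.tsv
heraldspec analyze g2    run.tags.tsv --gate 10000 --out g2.json
heraldspec analyze pn    run.tags.tsv --gate 10000 --out pn.tsv --summary pn.json

# lifetime fit (from a histogram table or directly from a stream)
heraldspec fit xcorr.tsv --irf-sigma 150 --out fit.json
heraldspec fit run.tags.tsv --from-stream --estimate-irf-from-residue

# end-to-end figure reproductions (desk-scale, seeded)
heraldspec reproduce fig1 --seed 1 --out outdir --report fig1.json
heraldspec reproduce fig2 --seed 1 --report fig2.json
heraldspec reproduce fig3 --seed 1 --report fig3.json
```

`ExperimentConfig` defaults follow the published operating point of the
experiment being reproduced: repetition rate 75.7 MHz, mean pair number
per pulse 0.0458, herald-arm efficiency 0.2804, lumped heralded
fluorescence efficiency 1.244e-4, fluorescence lifetime 1200 ps, IRF sigma
150 ps, gates 10 ns (fluorescence) / 6 ns (incident).  Desk-scale
reproductions boost the detection efficiencies and shorten durations so
runs complete in seconds; the statistics under test (conditional g²,
geometric P(N) shape, lifetime recovery) are efficiency-independent.

Two heralding laws are available (`herald_model`): the default
`"per-pulse"` flag model, under which the heralded pulses carry the
multi-photon weights `n_p^(M-1)/(1+n_p)^M` and the conditional g²(0)
follows `2n_p/(1+n_p)`, and a `"per-photon"` binary-click model
(`1-(1-eta)^M`), which number-weights the heralded ensemble.

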