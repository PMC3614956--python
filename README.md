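# aquaflux

Trajectory-analysis toolkit for gated water channels. Given a structure
(PDB, multi-model allowed), a coordinate trajectory (NAMD/CHARMM DCD or PDB
MODEL blocks) and a channel geometry, it computes:

- **Order parameters** — minimum-image distances (e.g. the His173:NE2 to
  Ser183 backbone-O distance D1, the His67:CB to Ile165:CD distance D2) and
  signed IUPAC dihedrals, per frame and per chain.
- **Gating states** — band classification of the order parameters with
  optional running-median smoothing and hysteresis (selectivity filter:
  wide/narrow; cytoplasmic end: open/intermediate/closed with the
  intermediate band at 6.5–7.5 Å), dwell segments, and two-letter joint
  labels (WO, NI, …).
- **Permeation** — complete water transits through the channel (mouth
  recrossings count zero), cumulative permeation curves, the one-directional
  rate q0, and the diffusive permeability `p_d = v_w · q0`.
- **Collective flux** — the dimensionless collective coordinate n(t) of all
  in-channel waters (one full transit advances n by exactly 1), its
  diffusion coefficient D_n from windowed-MSD regression (2 ns windows by
  default), the osmotic permeability `p_f = v_w · D_n`, channel occupancy
  N̄, and per-state permeability tables with the single-file consistency
  check `p_f/p_d` vs `N̄ + 1`.
- **Pore radius profiles** — deterministic maximal-sphere radius per z-slice
  (coarse grid + pattern-search refinement instead of a stochastic
  annealer), frame-averaged profiles, and radius-threshold state calls
  (filter wide above 1.1 Å; cytoplasmic end closed below 1.0 Å, open above
  1.4 Å).
- **Synthetic data** — single-file water trajectories (hop-process and
  Brownian collective modes) with exact permeability expectations and a
  hop-resolved transit log, telegraph order-parameter series with true
  labels, toy pores with analytic radii, and a minimal four-residue gating
  fixture built to requested distances/dihedrals. Everything downstream is
  testable without running any MD.

The MD protocol that would produce real inputs (NAMD 2.x, CHARMM36,
equilibrated membrane systems) is deliberately out of scope: this package
starts from trajectories.

## CLI

Full pipeline from a YAML config (channel z-bounds and, when a D1 series is
configured, the wide/narrow cutoff are mandatory — they are echoed into
every artifact header together with the config SHA-256):

```sh
aquaflux run -c config.yaml -o outdir
```

Example config:

```yaml
topology: system.pdb
trajectory: system.dcd        # optional; else PDB MODEL frames are used
frame_stride_ns: 0.1
channel: {z_lo: 15.0, z_hi: 31.0, buffer: 2.0, radial_cutoff: 6.0}
ops:
  - name: D1
    kind: distance
    atoms:
      - {residue_name: HIS, residue_number: 173, atom_name: NE2}
      - {residue_name: SER, residue_number: 183, atom_name: O}
  - name: D2
    kind: distance
    atoms:
      - {residue_name: HIS, residue_number: 67, atom_name: CB}
      - {residue_name: ILE, residue_number: 165, atom_name: CD}
classifier: {d1_cutoff: 6.0, d2_cuts: [6.5, 7.5], hysteresis: 0.2,
             smoothing_window: 5, min_dwell_ns: 1.0}
window_ns: 2.0
molar_volume: 18.0
```

Stage subcommands: `aquaflux ops|states|permeation|permeability|profile|convert`
and `aquaflux synth single-file|telegraph|pore` for fixtures, e.g.

```sh
aquaflux synth single-file --n-waters 7 --mode ctrw --rate 0.5 \
    --duration-ns 100 --seed 1 -o synth/
aquaflux permeability --topology synth/single_file.pdb \
    --trajectory synth/single_file.dcd --z-lo 15.09 --z-hi 29.09 \
    --buffer 0 --radial-cutoff 5 -o out/
aquaflux profile --topology pore.pdb --z-lo -10 --z-hi 10 --spacing 0.25 \
    --sf-z-range 5,9 --ce-z-range -9,-5 -o profile.csv
```

Permeabilities are reported in 10⁻¹⁴ cm³/s; report tables round
permeabilities to 2 decimals, occupancy to 1 decimal, and print undefined
ratios (p_d = 0) as "–".

## Conventions worth knowing

- Only orthorhombic boxes; triclinic cells are rejected so minimum-image
  arithmetic stays exact.
- Water z is continuity-unwrapped per molecule before region labeling, so
  periodic wrapping cannot fake a transit.
- Collective-coordinate membership is evaluated at the earlier frame of
  each step; MSD windows are non-overlapping with lags up to half a window
  and an OLS fit with free intercept.
- Isoleucine's delta carbon matches under both its "CD" and "CD1" PDB
  dialect names.
- Formats without timestamps get synthesized times at a configurable stride
  (default 0.1 ns/frame); every rate estimate therefore depends on an
  explicitly stated stride.
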