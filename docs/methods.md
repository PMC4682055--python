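# Methods

`chiralsheet` simulates an epithelial sheet as a vertex model with a
left–right (LR) asymmetric junctional tension, and quantifies the resulting
cell behaviour with the same statistics used on segmented microscopy data:
boundary-angle distributions, rose diagrams of intercalation axes, a planar
cell chirality (PCC) statistic, and directional cell velocities.  The target
system is the ring of epithelial cells that rotates unidirectionally around
the *Drosophila* genitalia, but every component is generic.

## The vertex model

Cells are polygons; the tissue state is the set of vertex positions
$\{\mathbf{x}_i\}$.  The energy is the standard form

$$E \;=\; \sum_{\text{cells }\alpha} \frac{K}{2}\,(A_\alpha - A_0)^2
\;+\; \sum_{\alpha} \frac{\Gamma}{2}\,P_\alpha^{\,2}
\;+\; \sum_{\text{junctions }ij} (\gamma_{ij} + \eta_{ij})\,\ell_{ij},$$

whose three terms represent the hydrostatic pressure of the cytoplasm (area
elasticity), perimeter contractility, and junctional line tension.  Vertices
obey overdamped dynamics with per-vertex friction,
$\mu_i\,\dot{\mathbf{x}}_i = \mathbf{F}_i = -\partial E/\partial \mathbf{x}_i$,
integrated with explicit Euler.  Friction encodes attachment to neighbouring
structures: border maps use $\mu=100$ for vertices attached to an immobile
layer and $\mu=1$ elsewhere ($\mu=\infty$ pins a vertex outright).

**Chiral line tension.**  LR asymmetry enters only through the
angle-dependent tension

$$\gamma_{ij} \;=\; \gamma_0\,\tfrac12\bigl(1 + \cos 2(\theta_{ij} - \theta_{\mathrm{pref}})\bigr),
\qquad \theta_{\mathrm{pref}} = +45^\circ,$$

where $\theta_{ij}$ is the signed acute angle between junction $ij$ and the
local anterior–posterior (AP) axis.  Contraction is maximal on boundaries
tilted $+45^\circ$ (right oblique) and vanishes at $-45^\circ$.  Setting
`enabled=False` gives the symmetric control $\gamma_{ij}=\gamma_0$;
`dispersion > 0` draws a per-junction preferred angle from
$\mathcal{N}(\theta_{\mathrm{pref}},\,\mathrm{dispersion}^2)$, modelling
broadly distributed polarity directions.

**Angle convention (global).**  The AP axis is a direction field: a fixed
unit vector for the flat strip, and "pointing from outside toward the
centre" for the ring.  $\theta$ is folded into $(-90^\circ, 90^\circ]$;
positive $\theta$ means tilted clockwise from the AP axis when the tissue is
drawn with the AP axis down the page ("right oblique"), and exactly
perpendicular boundaries fold to $+90^\circ$ (so ties at the fold are
classified right-oblique; histogram bins are half-open to avoid double
counting).  "Rightward" is the AP direction rotated $+90^\circ$, which for
the ring is one fixed tangential sense; the mirror experiment
($\theta_{\mathrm{pref}} \to -45^\circ$), not the absolute sense, is the
correctness guarantee.  For radial frames the AP direction is evaluated at
the edge midpoint, and velocity projections use the frame at each track
segment's start point.

**Frozen-γ forces.**  Because $\gamma_{ij}$ depends on $\theta_{ij}$ and
hence on vertex positions, the force is computed with $\gamma_{ij}$ frozen
at its current value — tension acts as a pulling force of magnitude
$\gamma_{ij}+\eta_{ij}$ along the junction.  The omitted angular-gradient
term can be switched on (`ChiralityParams.include_angle_gradient`) for
sensitivity analysis, in which case forces are the exact energy gradient in
both frames (verified against central finite differences to $10^{-4}$
relative; the default uniform-tension case is likewise an exact gradient).

**Tension noise.**  Fluctuating junctional shrinkage is modelled as an
Ornstein–Uhlenbeck offset $\eta_{ij}$ per junction with correlation time
$\tau$ and stationary standard deviation $\sigma$, updated exactly
($\eta' = \eta\,e^{-\Delta t/\tau} + \sigma\sqrt{1-e^{-2\Delta t/\tau}}\,\xi$),
so the effective noise strength is independent of the time step.

**Passive cells.**  Confining cells (the immobile neighbouring layer) are
flagged passive: they contribute no area or perimeter energy, junctions
they share with active cells still carry tension, and junctions between two
passive cells are inert.  All vertices of passive faces carry the border
role, so border friction acts on the attachment points of the peripheral
active cells — without this the zero-elasticity passive layer transmits no
anchoring at all.

## Junction remodelling (T1 transitions)

A junction is eligible for a T1 when it is shorter than
$\ell_{T1}$, borders two active faces of $\ge 4$ vertices, its endpoints are
3-valent with three incident faces each, and it is not in cooldown.  The
reconnection is atomic: the edge collapses to its midpoint and reopens
rotated $90^\circ$ at length $\mathrm{post\_factor}\times\ell_{T1}$; the two
formerly sharing cells separate and the two flanking cells gain a shared
boundary.  Rewiring is read off the loop order of the two sharing faces
(purely topological), and the reopened endpoints are placed on the side of
their new neighbours; V, E, F and the passive-face set are conserved by
construction.  Each event records $\theta$ of the shrinking boundary
immediately before reconnection — the quantity scored on intercalating
boundaries in film analysis.  Per pass, candidates are processed shortest
first (ties by junction id), the candidate set is recomputed after every
reconnection, and all junctions touching a T1 enter a cooldown of 10 steps,
which forbids immediate reversal.  The remodelled junction's noise offset is
reset to zero.

Defaults: $\ell_{T1} = 0.1\times$ the initial mean edge length,
post_factor 1.5, cooldown 10 steps.

**Excluded-volume floor.**  Junction classes that cannot relieve
contraction through a T1 (sheet-boundary edges, edges on the passive
interface, and just-remodelled edges in cooldown) could otherwise be driven
through zero length, inverting a polygon.  The scenario drivers therefore
enable a short-range repulsion between junction endpoints closer than
$0.5\,\ell_{T1}$ (force $k(1-\ell/\ell_{\mathrm{floor}})$, $k=1$).  It
engages only below the T1 trigger, so eligible junctions always remodel
before feeling it; it is a numerical guard, not a model ingredient, and is
off by default in `compute_forces`.

## Scenarios

Both scenarios run the same loop — noise update, forces, Euler step,
remodelling pass, snapshot — and are bitwise deterministic given the config
and seed.  Initial positions receive a seeded jitter of
$0.05\times$ the mean edge length so that the starting boundary-angle
census is balanced rather than locked to the three lattice directions
(a perfect lattice puts an entire edge family exactly on the $0^\circ$ or
$90^\circ$ classification boundary).

*Flat strip* (14 cells × 8 rows, hexagons of unit area, periodic in the
direction of motion): the top row is passive and attached to the upper
plate ($\mu_{\text{upper}}=100$ on all its vertices; $\mu=1$ elsewhere);
the AP axis is the fixed vector perpendicular to the strip.  Periodicity
removes end effects and matches the ring's closed topology.

*Annulus* (rings of cells between circles of radius 6 and 10, four active
rings plus one passive ring of 40 cells each, unit cell area): rings are
laid brick-wall fashion so radial-edge endpoints are 3-valent (a pure quad
grid would have 4-valent vertices and could never remodel).  The AP axis is
radial; inner-border vertices are confined to the inner circle and every
passive-ring vertex to its own initial radius by harmonic walls
($k_{\mathrm{wall}}=100$), with $\mu_{A7}=100$ on the passive ring.

Mechanical defaults ($K=1$, $A_0=1$, $\Gamma=0.04$, $\gamma_0=0.12$) place
the sheet in the standard soft-solid vertex-model regime; $dt=0.01$,
20 000 steps (200 time units), snapshots every 200 steps.  Both scenarios
use tension noise $\sigma=0.5\,\gamma_0$, $\tau=1$: this is the fluctuating
junctional shrinkage the ring model is defined with, and the flat sheet
needs the same fluctuation level to reach the remodelling threshold at all
— at $\sigma=0.04\,\gamma_0$ it freezes elastically with zero T1 events and
no sustained shear, because the maximal tension anisotropy
($\gamma_0=0.12$) balances against area elasticity before any junction
reaches $\ell_{T1}$.

With these conditions the chiral flat sheet shears one-sidedly (free rows
translate rightward, attached rows stay put), the chiral annulus rotates
steadily in the "rightward" tangential sense, mirrored chirality reverses
both with matched seeds, and the symmetric control shows no net drift.

## Quantification

* `boundary_angles` — one $\theta$ per scored boundary: mesh junctions
  (excluding passive–passive ones), or segmented-image boundaries
  (excluding those touching the image frame).
* `pcc_fraction` — the PCC census: $n$ in $(-90^\circ,0^\circ]$ (left) vs
  $(0^\circ,90^\circ]$ (right), with the right fraction and its binomial
  standard error.
* `rose_histogram` — half-open $30^\circ$ bins over $(-90^\circ,90^\circ]$.
* `intercalation_frequency` — $100\,n_{\mathrm{events}}/n_{\mathrm{boundaries}}$,
  rounded half-up to one decimal (each boundary counts once even if it
  remodels twice within the scoring window).
* `mean_tangential_velocity` — per frame pair, displacement projected onto
  the local rightward unit vector at the segment start; per-cell mean is
  total projected distance over total time; the grand mean averages cells.

## Imaging pipeline

`extract_boundaries` consumes an integer label mask (0 = boundary lines,
positive = cell regions) produced by any external segmentation.  Zero
pixels with exactly two distinct positive 8-neighbours join that region
pair's boundary; pixels with three or more become vertex candidates,
clustered within 2 px (boundary lines are ~1 px wide, so triple contacts
smear over at most ~2 px).  A boundary's angle is the chord between its two
incident vertices — matching "the line formed by each cell boundary" rather
than a pixel-wise fit — with extremal-pixel fallback where a boundary meets
the tissue rim; vertex-cluster pixels belong to no boundary, so they are
excluded from all intensity means.  Image row/col is converted to y-up
coordinates before any angle computation so one sign convention governs the
whole codebase.  `boundary_intensity` normalises each boundary's mean
intensity by the mean over all boundaries (the normalised ratios average to
1 exactly), bins by $\theta$ at $30^\circ$, and reports left/right
aggregate means.  The watershed transform itself, seed selection and cell
tracking are out of scope — the pipeline starts from labelled masks.

## Synthetic data

The generators provide ground truth for every quantification stage, with no
external data:

* `make_chiral_mesh` — a hexagonal sheet under simple shear $x \to x + sy$
  (shear preserves polygon validity trivially), with a small jitter to break
  the classification ties of the perfect lattice.  The returned
  right-fraction is obtained by exhaustively classifying every generated
  edge; no closed-form shortcut is used.
* `render_labeled_tissue` — nearest-pixel rasterisation of a mesh into a
  label mask with 1-px carved boundary lines (deterministic tie-breaking:
  faces scanned in index order, lines carved where the right/down neighbour
  differs), plus an intensity channel
  $\mathrm{background}\times(1 + b\cos 2(\theta - 45^\circ))$ on boundary
  pixels, vertex pixels at background, optional Gaussian noise.
* `make_drift_tracks` — tracks $\mathbf{x}_t = \mathbf{x}_0 + t(v, 0)$ plus
  isotropic noise.

What the generators do **not** emulate: curved boundaries, segmentation
errors, point-spread blur, bleaching, uneven illumination, cell divisions
or extrusions, and tracking mistakes.  Tests passing on these fixtures
demonstrate that the statistics are computed correctly and that the
geometry pipeline is self-consistent — not that the pipeline is robust to
real microscopy artefacts.

## Numerical choices and degenerate inputs

* Explicit Euler at $dt=0.01$ with the default moduli; non-finite positions
  raise an instability error advising a smaller step.
* The fold maps $-90^\circ \to +90^\circ$ with a $10^{-9}$-degree snap
  tolerance; zero-length edges raise a degenerate-input error.
* T1 tie-breaking is (length, junction id); all random draws flow from one
  `numpy` generator per run, so trajectories are reproducible bitwise.
* Mesh validation checks windings, simple polygons (via `shapely`),
  junction/face incidence, and the Euler characteristic of the scenario's
  topology class (patch 1, cylinder/annulus 0).
* Ensemble sizes (8 seeds, 20 000 steps, 14×8 and 200-cell meshes) keep a
  full acceptance sweep within minutes on one core while producing
  hundreds of pooled T1 events.

## Known limitations

* No cell division, extrusion or apoptosis; the inner confining circle is
  static, so the posterior half-rotation of the real organ is not modelled.
* The perimeter term is $\Gamma P^2/2$ (no preferred perimeter $P_0$); with
  the soft-solid defaults this is the conventional choice, but a
  $(P-P_0)^2$ variant would change the tension scale needed for
  remodelling.
* Confinement is a stiff spring rather than a rigid constraint.
* The flat strip is periodic sideways; open-ended strips would add end
  effects the model does not attempt to capture.
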