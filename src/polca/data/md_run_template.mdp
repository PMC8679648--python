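; Documented NpT bulk-liquid run template for the exported topologies.
; This file is a reference configuration, not executed by the package.
;
; Parametrization runs: 10 ns (20 ns for silanol-containing molecules);
; validation runs: 50 ns (100 ns for silanols); discard the first 0.5 ns.
integrator               = md            ; leapfrog
dt                       = 0.002         ; 2 fs time step
nsteps                   = 5000000       ; 10 ns (double for silanols)
;
constraints              = all-bonds     ; every bond is a rigid constraint
constraint-algorithm     = lincs
;
cutoff-scheme            = Verlet
rlist                    = 1.0
vdwtype                  = cut-off
rvdw                     = 1.0           ; nm
DispCorr                 = EnerPres      ; long-range dispersion corrections
coulombtype              = PME           ; particle-mesh Ewald
rcoulomb                 = 1.0
;
tcoupl                   = v-rescale
tc-grps                  = System
tau-t                    = 0.1           ; ps
ref-t                    = 298           ; K
pcoupl                   = Parrinello-Rahman
tau-p                    = 2.0           ; ps
compressibility          = 4.5e-5
ref-p                    = 1.0           ; bar
;
; Gas-phase reference runs: single molecule, NVT (pcoupl = no), no
; periodic boundary conditions, no cutoffs.
;
; Free-energy runs add a stochastic-dynamics integrator and the lambda
; schedules: 16 LJ states (0, 0.05 ... 0.5, 0.6 ... 1) with soft-core
; sc-alpha 0.5, sc-power 1, sc-sigma 0.3, and 6 electrostatic states
; (0, 0.2, 0.4, 0.6, 0.8, 1) with sc-alpha 0.
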