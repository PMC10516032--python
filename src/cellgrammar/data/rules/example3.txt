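# Tumor attackers and defenders: CD8 T cell killing modulated by
# macrophage-secreted pro-/anti-inflammatory factors.
In tumor cells:
oxygen increases cycle entry from 0 towards 0.00072 with a Hill response, with half-max 21.5 and Hill power 4.
pressure decreases cycle entry from 0 towards 0 with a Hill response, with half-max 1 and Hill power 4.
oxygen decreases necrosis from 0.0028 towards 0 with a Hill response, with half-max 3.75 and Hill power 8.
damage increases apoptosis from 7.2e-05 towards 0.072 with a Hill response, with half-max 180 and Hill power 2.
dead increases debris secretion from 0 towards 0.017 with a Hill response, with half-max 0.1 and Hill power 10. Rule applies to dead cells.
In macrophage cells:
oxygen increases pro-inflammatory factor secretion from 0 towards 10 with a Hill response, with half-max 5 and Hill power 4.
oxygen decreases anti-inflammatory factor secretion from 10 towards 0 with a Hill response, with half-max 5 and Hill power 4.
In CD8 T cell cells:
anti-inflammatory factor decreases attack tumor from 0.1 towards 0 with a Hill response, with half-max 0.5 and Hill power 8.
pro-inflammatory factor increases attack tumor from 0.1 towards 1 with a Hill response, with half-max 0.5 and Hill power 8.
anti-inflammatory factor decreases migration speed from 1 towards 0 with a Hill response, with half-max 0.5 and Hill power 8.
contact with tumor decreases migration speed from 1 towards 0 with a Hill response, with half-max 0.5 and Hill power 2.
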