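# Hypoxia-driven growth and a transient post-hypoxic migratory phenotype.
In tumor cells:
oxygen increases cycle entry from 1.7e-05 towards 0.0007 with a Hill response, with half-max 21.5 and Hill power 4.
pressure decreases cycle entry from 1.7e-05 towards 0 with a Hill response, with half-max 0.25 and Hill power 3.
oxygen decreases necrosis from 0.0028 towards 0 with a Hill response, with half-max 3.75 and Hill power 8.
oxygen decreases transform to motile tumor from 0.001 towards 0 with a Hill response, with half-max 6.75 and Hill power 8.
In motile tumor cells:
oxygen increases cycle entry from 1.7e-05 towards 0.0007 with a Hill response, with half-max 21.5 and Hill power 4.
pressure decreases cycle entry from 1.7e-05 towards 0 with a Hill response, with half-max 0.25 and Hill power 3.
oxygen decreases necrosis from 0.0028 towards 0 with a Hill response, with half-max 3.75 and Hill power 8.
oxygen increases transform to tumor from 0 towards 0.005 with a Hill response, with half-max 6.75 and Hill power 8.
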