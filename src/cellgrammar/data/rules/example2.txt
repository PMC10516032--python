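# Fibroblast-contact-driven EMT in a pancreatic tumor microenvironment.
In epithelial_normal cells:
contact with fibroblast increases transform to mesenchymal_normal from 0 towards 0.01 with a Hill response, with half-max 0.01 and Hill power 4.
In mesenchymal_normal cells:
ecm decreases migration speed from 0 towards 0 with a Hill response, with half-max 0.5 and Hill power 4.
inflammatory_signal decreases transform to epithelial_normal from 0.01 towards 0 with a Hill response, with half-max 0.2 and Hill power 4.
In epithelial_tumor cells:
pressure decreases cycle entry from 0.001 towards 0 with a Hill response, with half-max 1 and Hill power 4.
contact with fibroblast increases transform to mesenchymal_tumor from 0 towards 0.01 with a Hill response, with half-max 0.01 and Hill power 4.
In mesenchymal_tumor cells:
ecm decreases migration speed from 0 towards 0 with a Hill response, with half-max 0.5 and Hill power 4.
inflammatory_signal decreases transform to epithelial_tumor from 0.01 towards 0 with a Hill response, with half-max 0.2 and Hill power 4.
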