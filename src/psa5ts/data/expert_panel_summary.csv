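domain,cvi,mean_importance,printed_fip
pain,0.98,2.93,287.14
fatigue,0.90,2.16,194.40
functional capacity,0.88,2.18,193.60
skin problems,0.87,2.20,191.40
depressive mood,0.71,2.01,142.71
patient global assessment,0.68,1.87,127.16
ability to work and for leisure,0.63,1.83,115.29
sleep disturbance,0.61,1.82,111.02
feeling of discomfort,0.56,1.60,89.60
anxiety fear and uncertainty,0.55,1.61,88.55
embarrassment or shame,0.52,1.65,85.80
social participation,0.49,1.69,82.81
relationship with family,0.47,1.60,75.20
concentration difficulties,0.45,1.58,71.10
sexual life,0.40,1.80,72.00
coping,0.37,1.61,63.27
financial impact,0.35,1.70,59.50
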