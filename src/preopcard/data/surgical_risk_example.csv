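procedure,level
cataract extraction,low
carpal tunnel release,low
cystoscopy,low
breast lumpectomy,low
inguinal hernia repair,moderate
laparoscopic cholecystectomy,moderate
total knee arthroplasty,moderate
total hip arthroplasty,moderate
colectomy,moderate
prostatectomy,moderate
open aortic repair,high
major intraperitoneal resection,high
carotid endarterectomy,high
suprainguinal vascular bypass,high
pneumonectomy,high
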