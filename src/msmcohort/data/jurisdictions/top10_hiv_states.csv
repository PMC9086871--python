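# The ten US states with the highest numbers of new HIV diagnoses
# (CDC HIV surveillance, 2019 reporting round). Editable fixture.
kind,name,state
state,Florida,FL
state,California,CA
state,Texas,TX
state,Georgia,GA
state,New York,NY
state,North Carolina,NC
state,Illinois,IL
state,Ohio,OH
state,Pennsylvania,PA
state,Maryland,MD
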