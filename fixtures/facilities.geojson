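{"type": "FeatureCollection", "features": [{"type": "Feature", "geometry": {"type": "Point", "coordinates": [500.0, 0.0]}, "properties": {"facility_id": "D01"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [1000.0, 0.0]}, "properties": {"facility_id": "D02"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [1500.0, 0.0]}, "properties": {"facility_id": "D03"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [2000.0, 0.0]}, "properties": {"facility_id": "D04"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [0.0, 400.0]}, "properties": {"facility_id": "D05"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [500.0, 400.0]}, "properties": {"facility_id": "D06"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [1000.0, 400.0]}, "properties": {"facility_id": "D07"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [1500.0, 400.0]}, "properties": {"facility_id": "D08"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [2000.0, 400.0]}, "properties": {"facility_id": "D09"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [0.0, 800.0]}, "properties": {"facility_id": "D10"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [500.0, 800.0]}, "properties": {"facility_id": "D11"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [1000.0, 800.0]}, "properties": {"facility_id": "D12"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [1500.0, 800.0]}, "properties": {"facility_id": "D13"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [32500.0, 0.0]}, "properties": {"facility_id": "K01"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [35000.0, 0.0]}, "properties": {"facility_id": "K02"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [37500.0, 0.0]}, "properties": {"facility_id": "K03"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [40000.0, 0.0]}, "properties": {"facility_id": "K04"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [42500.0, 0.0]}, "properties": {"facility_id": "K05"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [30000.0, 2000.0]}, "properties": {"facility_id": "K06"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [32500.0, 2000.0]}, "properties": {"facility_id": "K07"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [35000.0, 2000.0]}, "properties": {"facility_id": "K08"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [37500.0, 2000.0]}, "properties": {"facility_id": "K09"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [40000.0, 2000.0]}, "properties": {"facility_id": "K10"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [42500.0, 2000.0]}, "properties": {"facility_id": "K11"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [30000.0, 4000.0]}, "properties": {"facility_id": "K12"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [32500.0, 4000.0]}, "properties": {"facility_id": "K13"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [35000.0, 4000.0]}, "properties": {"facility_id": "K14"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [37500.0, 4000.0]}, "properties": {"facility_id": "K15"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [40000.0, 4000.0]}, "properties": {"facility_id": "K16"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [42500.0, 4000.0]}, "properties": {"facility_id": "K17"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [30000.0, 6000.0]}, "properties": {"facility_id": "K18"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [32500.0, 6000.0]}, "properties": {"facility_id": "K19"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [35000.0, 6000.0]}, "properties": {"facility_id": "K20"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [37500.0, 6000.0]}, "properties": {"facility_id": "K21"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [40000.0, 6000.0]}, "properties": {"facility_id": "K22"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [42500.0, 6000.0]}, "properties": {"facility_id": "K23"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [30000.0, 8000.0]}, "properties": {"facility_id": "K24"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [32500.0, 8000.0]}, "properties": {"facility_id": "K25"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [35000.0, 8000.0]}, "properties": {"facility_id": "K26"}}, {"type": "Feature", "geometry": {"type": "Point", "coordinates": [31000.0, 9000.0]}, "properties": {"facility_id": "K00"}}]}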